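strain_id	genome_name	patric_genome_id	genbank_accession	country	n_contigs	length	gc	n_cds
M21-2	Faecalibacterium prausnitzii M21/2	411485.10	ABED00000000	United Kingdom	25	3,125,761	56.3	2,776
SL3-3	Faecalibacterium prausnitzii SL3/3	657322.3	FP929046	United Kingdom	1	3,214,418	54.81	3,052
L2-6	Faecalibacterium prausnitzii L2-6	718252.3	FP929045	United Kingdom	1	3,321,367	55.57	3,232
KLE1255	Faecalibacterium cf. prausnitzii KLE1255	748224.3	AECU00000000	USA	139	2,907,000	56.27	2,783
AHMP-21	Faecalibacterium prausnitzii AHMP_21	853.123	NOUV00000000	Australia	85	3,019,317	57.36	3,201
HMI-19	Faecalibacterium prausnitzii HMI_19	853.124	NOUW00000000	Australia	63	2,879,169	56.82	2,933
CNCM_I_4540	Faecalibacterium prausnitzii CNCM_4540	853.62	NMTQ00000000	France	48	3,043,568	55.7	3,206
CNCM_I_4541	Faecalibacterium prausnitzii CNCM_4541	853.63	NMTR00000000	France	78	2,822,838	58.11	2,825
CNCM_I_4542	Faecalibacterium prausnitzii CNCM_4542	853.64	NMTS00000000	France	106	2,914,466	55.83	3,071
CNCM_I_4543	Faecalibacterium prausnitzii CNCM_4543	853.65	NMTT00000000	France	22	3,080,452	56.2	3,223
CNCM_I_4544	Faecalibacterium prausnitzii CNCM_4544	853.66	NMTU00000000	France	71	2,808,526	55.98	2,907
CNCM_I_4546	Faecalibacterium prausnitzii CNCM_4546	853.67	NMTV00000000	France	244	3,422,520	54.88	3,611
CNCM_I_4573	Faecalibacterium prausnitzii CNCM_4573	853.68	NMTW00000000	France	83	3,275,249	55.9	3,479
CNCM_I_4574	Faecalibacterium prausnitzii CNCM_4574	853.69	NMTX00000000	France	38	3,088,985	56.26	3,249
CNCM_I_4575	Faecalibacterium prausnitzii CNCM_4575	853.70	NMTY00000000	France	37	3,006,602	57.51	3,077
CNCM_I_4644	Faecalibacterium prausnitzii CNCM_4644	853.71	NMTZ00000000	France	36	2,915,240	56.37	3,019
A2-165_PacBio	Faecalibacterium prausnitzii A2-165_PacBio	853.73	CP022479	France	1	3,110,044	56.33	3,231
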