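"""Synthetic genome cohorts with known cluster structure.

A root gene pool (shared core) is mutated into per-cluster ancestors, which
are mutated again into strains; each cluster also carries its own accessory
genes and every strain gets private singleton genes.  Substitutions are
resampled per site (no multiple-hit modelling), which is adequate for the
divergence regime used here (d <= ~0.15) and keeps the truth bookkeeping
exact.  No indels are introduced, so homologous genes stay positionally
aligned and expected identities follow directly from the branch substitution
probabilities.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .core_io import GenomeRecord, write_fasta

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                 if a + b + c not in _STOPS]

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _i
_DECODE_TABLE = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass
class SimConfig:
    n_clusters: int = 3
    genomes_per_cluster: tuple[int, ...] = (5, 4, 4)
    n_singleton_strains: int = 4
    core_genes: int = 60
    cluster_accessory: int = 12
    private_genes_mean: float = 6.0
    gene_len_mean: int = 300
    gene_len_sd: int = 60
    gene_len_min: int = 150
    intergenic_len_mean: int = 40
    d_within: float = 0.02
    d_between: float = 0.13
    ts_tv_kappa: float = 2.0
    gene_loss_prob: float = 0.02
    contigs_per_genome: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.genomes_per_cluster) != self.n_clusters:
            raise ValueError("genomes_per_cluster must have n_clusters entries")
        if not (0 <= self.d_within < self.d_between <= 0.3):
            raise ValueError("require 0 <= d_within < d_between <= 0.3")
        for name in ("n_clusters", "n_singleton_strains", "core_genes",
                     "cluster_accessory"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "genomes_per_cluster" in data:
            data["genomes_per_cluster"] = tuple(data["genomes_per_cluster"])
        return cls(**data)


@dataclass
class TruthTable:
    strain_cluster: dict[str, str]                 # strain -> cluster label or "singleton"
    gene_family: dict[str, dict[str, str]]         # strain -> gene_id -> family_id
    expected_identity: dict[frozenset, float]      # pair -> expected percent identity

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for strain, cl in self.strain_cluster.items():
            if cl != "singleton":
                out.setdefault(cl, set()).add(strain)
        return out

    def core_family_count(self) -> int:
        per_strain = [set(inv.values()) for inv in self.gene_family.values()]
        return len(set.intersection(*per_strain)) if per_strain else 0


@dataclass
class Cohort:
    genomes: dict[str, GenomeRecord]
    genes: dict[str, dict[str, str]]       # strain -> gene_id -> nt sequence
    proteins: dict[str, dict[str, str]]    # strain -> gene_id -> aa sequence
    truth: TruthTable
    config: SimConfig

    @property
    def strain_ids(self) -> list[str]:
        return list(self.genomes)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def mutate(sequence: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``d``.

    Given a substitution, a transition is chosen with odds ``kappa : 2``
    against the two transversions.  Length is preserved; ``N`` sites are left
    untouched.
    """
    if not 0 <= d <= 0.75:
        raise ValueError("d must be in [0, 0.75]")
    if d == 0 or not sequence:
        return sequence
    codes = _ENCODE_TABLE[np.frombuffer(sequence.encode(), dtype=np.uint8)].copy()
    valid = codes != 255
    hit = (rng.random(len(codes)) < d) & valid
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return sequence
    old = codes[idx]
    is_transition = rng.random(len(idx)) < kappa / (kappa + 2.0)
    new = old.copy()
    new[is_transition] = (old[is_transition] + 2) % 4
    tv = ~is_transition
    # transversion targets: the two bases of opposite purine/pyrimidine class,
    # i.e. (b+1)%4 and (b+3)%4 under the A=0,C=1,G=2,T=3 encoding
    step = np.where(rng.integers(0, 2, size=int(tv.sum())) == 0, 1, 3).astype(np.uint8)
    new[tv] = (old[tv] + step) % 4
    codes[idx] = new
    out = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    out[valid] = _DECODE_TABLE[codes[valid]]
    return out.tobytes().decode()


def _repair_internal_stops(mutated: str, original: str) -> str:
    """Redirect any substitution that created an internal stop codon to a
    different non-stop target base.

    The site stays substituted, so the expected per-site divergence is
    unchanged (unlike reverting, which would bias identity upward).
    """
    if mutated == original:
        return mutated
    out = list(mutated)
    # every codon but the terminal stop must stay stop-free (including the
    # start codon, whose mutation would otherwise translate to '*')
    for i in range(0, len(mutated) - 3, 3):
        codon = mutated[i : i + 3]
        if codon not in _STOPS:
            continue
        repaired = False
        for p in range(3):
            if repaired:
                break
            if codon[p] == original[i + p]:
                continue
            for cand in "ACGT":
                if cand in (original[i + p], codon[p]):
                    continue
                if codon[:p] + cand + codon[p + 1 :] not in _STOPS:
                    out[i + p] = cand
                    repaired = True
                    break
        # a stop can only arise from at least one substitution, and one of the
        # two alternative targets is always non-stop, so repaired is True here
    return "".join(out)


def _mutate_gene(gene: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    return _repair_internal_stops(mutate(gene, d, kappa, rng), gene)


# ---------------------------------------------------------------------------
# ancestral pool
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, length: int) -> str:
    """Random ORF: ATG start, random sense codons, one terminal stop."""
    n_codons = max(length // 3, 3)
    body = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _random_gene_length(config: SimConfig, rng: np.random.Generator) -> int:
    raw = rng.normal(config.gene_len_mean, config.gene_len_sd)
    return max(config.gene_len_min, 3 * int(round(raw / 3.0)))


def _random_spacer(config: SimConfig, rng: np.random.Generator) -> str:
    length = max(1, int(round(rng.exponential(config.intergenic_len_mean))))
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_ancestor(config: SimConfig, rng: np.random.Generator | None = None):
    """Ancestral core gene pool plus genome layout.

    Returns ``(genes, spacers)``: ``genes`` maps family id to ORF sequence in
    layout order, and ``spacers`` maps ``"lead"`` plus every family id to the
    intergenic sequence that follows it.  Tying each spacer to its gene keeps
    strains collinear downstream of a gene loss (the gene and its spacer are
    lost as one unit).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = {f"CORE{i:04d}": _random_orf(rng, _random_gene_length(config, rng))
             for i in range(config.core_genes)}
    spacers = {"lead": _random_spacer(config, rng)}
    for fam in genes:
        spacers[fam] = _random_spacer(config, rng)
    return genes, spacers


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _translate(gene: str) -> str:
    aa = str(Seq(gene).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise AssertionError("internal stop in simulated gene")
    return aa


def _assemble(lead: str, units: list[tuple[str, str]]) -> str:
    """Concatenate the leading spacer with (gene, trailing spacer) units."""
    parts = [lead]
    for gene, spacer in units:
        parts.append(gene)
        parts.append(spacer)
    return "".join(parts)


def _split_contigs(sequence: str, n: int, rng: np.random.Generator) -> list[str]:
    if n <= 1 or len(sequence) <= n:
        return [sequence]
    cuts = np.sort(rng.choice(np.arange(1, len(sequence)), size=n - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate the full cohort; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    core_genes, core_spacers = simulate_ancestor(config, rng)

    half_between = config.d_between / 2.0
    half_within = config.d_within / 2.0
    kappa = config.ts_tv_kappa

    # per-lineage substitution probability from the root
    branch: dict[str, float] = {}
    strain_cluster: dict[str, str] = {}
    strain_pool: dict[str, dict[str, str]] = {}      # strain -> family -> gene seq
    strain_spacers: dict[str, dict[str, str]] = {}   # strain -> "lead"/family -> spacer

    def _descend(genes: dict[str, str], spacers: dict[str, str], d: float):
        new_genes = {fam: _mutate_gene(seq, d, kappa, rng)
                     for fam, seq in genes.items()}
        new_spacers = {key: mutate(s, d, kappa, rng) for key, s in spacers.items()}
        return new_genes, new_spacers

    for ci in range(config.n_clusters):
        label = f"cluster{ci + 1}"
        anc_genes, anc_spacers = _descend(core_genes, core_spacers, half_between)
        for ai in range(config.cluster_accessory):
            fam = f"ACC{ci + 1}_{ai:03d}"
            anc_genes[fam] = _random_orf(rng, _random_gene_length(config, rng))
            anc_spacers[fam] = _random_spacer(config, rng)
        for si in range(config.genomes_per_cluster[ci]):
            strain = f"c{ci + 1}_s{si + 1}"
            strain_cluster[strain] = label
            branch[strain] = 1.0 - (1.0 - half_between) * (1.0 - half_within)
            strain_pool[strain], strain_spacers[strain] = _descend(
                anc_genes, anc_spacers, half_within)

    for ui in range(config.n_singleton_strains):
        strain = f"sing_{ui + 1}"
        strain_cluster[strain] = "singleton"
        branch[strain] = half_between
        strain_pool[strain], strain_spacers[strain] = _descend(
            core_genes, core_spacers, half_between)

    genomes: dict[str, GenomeRecord] = {}
    genes_out: dict[str, dict[str, str]] = {}
    proteins_out: dict[str, dict[str, str]] = {}
    gene_family: dict[str, dict[str, str]] = {}

    for strain, pool in strain_pool.items():
        families = list(pool)
        if config.gene_loss_prob > 0 and len(families) > 1:
            keep_mask = rng.random(len(families)) >= config.gene_loss_prob
            if not keep_mask.any():
                keep_mask[0] = True
            kept = [fam for fam, k in zip(families, keep_mask) if k]
        else:
            kept = families
        n_private = int(rng.poisson(config.private_genes_mean))
        private = {f"PRIV_{strain}_{pi:03d}": _random_orf(
            rng, _random_gene_length(config, rng)) for pi in range(n_private)}

        spacers = strain_spacers[strain]
        gene_seqs: dict[str, str] = {}
        fam_of: dict[str, str] = {}
        units: list[tuple[str, str]] = []
        for gi, fam in enumerate(kept):
            gid = f"{strain}_g{gi + 1:04d}"
            gene_seqs[gid] = pool[fam]
            fam_of[gid] = fam
            units.append((pool[fam], spacers[fam]))
        for pj, (fam, seq) in enumerate(private.items()):
            gid = f"{strain}_p{pj + 1:04d}"
            gene_seqs[gid] = seq
            fam_of[gid] = fam
            units.append((seq, _random_spacer(config, rng)))
        if not units:
            raise ValueError(f"configuration produced an empty genome for {strain}")

        sequence = _assemble(spacers["lead"], units)
        contigs = _split_contigs(sequence, config.contigs_per_genome, rng)
        genomes[strain] = GenomeRecord(strain_id=strain, contigs=contigs)
        genes_out[strain] = gene_seqs
        proteins_out[strain] = {gid: _translate(seq) for gid, seq in gene_seqs.items()}
        gene_family[strain] = fam_of

    expected = {}
    same_target = _p_same_target(kappa)
    strains = list(genomes)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            if strain_cluster[a] == strain_cluster[b] != "singleton":
                pa = pb = half_within
            else:
                pa, pb = branch[a], branch[b]
            ident = (1 - pa) * (1 - pb) + pa * pb * same_target
            expected[frozenset((a, b))] = 100.0 * ident

    truth = TruthTable(strain_cluster, gene_family, expected)
    return Cohort(genomes, genes_out, proteins_out, truth, config)


def _p_same_target(kappa: float) -> float:
    """Probability two independent substitutions of the same base coincide."""
    p_ts = kappa / (kappa + 2.0)
    p_tv = (1.0 - p_ts) / 2.0
    return p_ts ** 2 + 2 * p_tv ** 2


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write genome/gene/protein FASTA sets, truth.tsv and simconfig.json."""
    out_dir = str(out_dir)
    for sub in ("genomes", "genes", "proteins"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for strain, genome in cohort.genomes.items():
        write_fasta(os.path.join(out_dir, "genomes", f"{strain}.fna"),
                    [(f"{strain}_contig{i + 1}", c) for i, c in enumerate(genome.contigs)])
        write_fasta(os.path.join(out_dir, "genes", f"{strain}.ffn"),
                    sorted(cohort.genes[strain].items()))
        write_fasta(os.path.join(out_dir, "proteins", f"{strain}.faa"),
                    sorted(cohort.proteins[strain].items()))
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("strain\tcluster\tgene_id\tfamily_id\n")
        for strain in cohort.genomes:
            cluster = cohort.truth.strain_cluster[strain]
            for gid, fam in sorted(cohort.truth.gene_family[strain].items()):
                fh.write(f"{strain}\t{cluster}\t{gid}\t{fam}\n")
    with open(os.path.join(out_dir, "simconfig.json"), "w") as fh:
        fh.write(cohort.config.to_json())


def load_cohort_dir(path) -> tuple[dict[str, GenomeRecord], dict[str, dict[str, str]] | None, dict[str, dict[str, str]] | None]:
    """Load genomes (and genes/proteins if present) from a cohort directory
    laid out as written by :func:`write_cohort`."""
    from .core_io import read_fasta

    path = str(path)
    genome_dir = os.path.join(path, "genomes")
    base = genome_dir if os.path.isdir(genome_dir) else path
    genomes: dict[str, GenomeRecord] = {}
    for fname in sorted(os.listdir(base)):
        if fname.endswith((".fna", ".fa", ".fasta")):
            rec = GenomeRecord.from_fasta(os.path.join(base, fname))
            genomes[rec.strain_id] = rec

    def load_sets(sub, exts):
        d = os.path.join(path, sub)
        if not os.path.isdir(d):
            return None
        out = {}
        for fname in sorted(os.listdir(d)):
            if fname.endswith(exts):
                sid = fname.rsplit(".", 1)[0]
                out[sid] = dict(read_fasta(os.path.join(d, fname), alphabet="any"))
        return out or None

    genes = load_sets("genes", (".ffn",))
    proteins = load_sets("proteins", (".faa",))
    return genomes, genes, proteins
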