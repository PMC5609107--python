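"""End-to-end orchestration: cohort in, genospecies report out.

Stage artifacts are written under the output directory with a sha256
manifest; each stage derives its own seed as ``seed + stage_index`` so reruns
with the same config are byte-identical (modulo nothing: no timestamps go
into artifacts).
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .align import AlignParams
from .ani import AniConfig, ani_matrix, single_linkage_clusters, ClusterAssignment
from .core_io import (LabeledMatrix, cohort_summary, export_nexus_distances,
                      load_table1, load_table2_ani, round_half_up)
from .fragsim import FragmentationScheme, distance_matrix, similarity_matrix
from .heaps import fit_decay, fit_heaps, permute_accumulate, species_support
from .pangenome import build_graph, mcl, subsets
from .simulate import Cohort, SimConfig, load_cohort_dir, simulate_cohort, write_cohort
from .wgmlst import (GENE_PARAMS, build_locus_db, call_alleles,
                     profile_distance_matrix, profiles_to_table, upgma)

logger = logging.getLogger("genospecies")

#: engine parameters tuned for the no-indel simulated cohorts: everything
#: runs on the deterministic seeded gapless route
FAST_NT_PARAMS = AlignParams(kmer_size=11, exact_threshold=11)

_STAGES = ("simulate", "fragsim", "ani", "wgmlst", "pangenome", "heaps")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                # "simulate" | "genomes-dir"
    input_dir: str | None = None          # cohort directory for genomes-dir mode
    out_dir: str = "genospecies_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    frag_scheme: FragmentationScheme = field(default_factory=FragmentationScheme)
    ani: AniConfig = field(default_factory=AniConfig)
    wgmlst_min_identity: float = 90.0
    wgmlst_min_coverage: float = 80.0
    pangenome_min_identity: float = 40.0
    pangenome_min_coverage: float = 50.0
    inflation: float = 1.5
    n_perms: int = 100
    support_margin: float = 0.02

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data:
            data["sim"] = SimConfig.from_dict(data["sim"])
        if "frag_scheme" in data:
            data["frag_scheme"] = FragmentationScheme(**data["frag_scheme"])
        if "ani" in data:
            data["ani"] = AniConfig(**data["ani"])
        return cls(**data)

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def stage_seed(self, stage: str) -> int:
        return self.seed + _STAGES.index(stage)


def _write(path, text: str) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(text)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the genospecies report (also written to
    ``report.json`` in the output directory)."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: list[str] = []
    t_start = time.monotonic()

    def stage_done(name: str, **counts):
        logger.info("stage %-10s %6.1fs %s", name,
                    time.monotonic() - t_start,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    # --- cohort -----------------------------------------------------------
    if config.mode == "simulate":
        sim_cfg = SimConfig.from_dict({**asdict(config.sim),
                                       "seed": config.stage_seed("simulate")})
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, os.path.join(out, "cohort"))
        genomes, genes, proteins = cohort.genomes, cohort.genes, cohort.proteins
        truth = cohort.truth
    elif config.mode == "genomes-dir":
        if not config.input_dir:
            raise ValueError("genomes-dir mode requires input_dir")
        genomes, genes, proteins = load_cohort_dir(config.input_dir)
        truth = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    if len(genomes) < 2:
        raise ValueError("cohort must contain >= 2 genomes")
    stage_done("simulate", genomes=len(genomes))

    stats = cohort_summary(pd.DataFrame(
        [{"strain_id": s, "length": g.length, "gc": g.gc,
          "n_contigs": len(g.contigs)} for s, g in genomes.items()]))
    stats.rows.to_csv(os.path.join(out, "cohort_stats.tsv"), sep="\t", index=False)
    artifacts.append("cohort_stats.tsv")

    # --- fragmented similarity -------------------------------------------
    sim_matrix = similarity_matrix(genomes, config.frag_scheme, FAST_NT_PARAMS)
    sim_matrix.to_tsv(os.path.join(out, "fragsim_similarity.tsv"))
    dist = distance_matrix(sim_matrix)
    export_nexus_distances(dist, os.path.join(out, "fragsim_distance.nexus"))
    artifacts += ["fragsim_similarity.tsv", "fragsim_distance.nexus"]
    stage_done("fragsim")

    # --- ANI + clustering -------------------------------------------------
    ani = ani_matrix(genomes, config.ani, FAST_NT_PARAMS)
    ani.to_tsv(os.path.join(out, "ani_matrix.tsv"))
    assignment = single_linkage_clusters(ani, config.ani.cutoff)
    _write(os.path.join(out, "ani_clusters.json"), assignment.to_json())
    artifacts += ["ani_matrix.tsv", "ani_clusters.json"]
    stage_done("ani", clusters=len(assignment.clusters),
               singletons=len(assignment.singletons))

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.to_json().encode()).hexdigest(),
        },
        "cohort": {
            "n_genomes": len(genomes),
            "length_range": stats.length_range,
            "gc_min": stats.gc_min,
            "gc_max": stats.gc_max,
        },
        "ani": assignment.to_dict(),
    }
    if truth is not None:
        report["truth_clusters"] = {k: sorted(v)
                                    for k, v in truth.clusters().items()}

    # --- wgMLST -----------------------------------------------------------
    if genes is not None:
        db = build_locus_db(genes, GENE_PARAMS,
                            config.wgmlst_min_identity, config.wgmlst_min_coverage)
        profiles = [call_alleles(genes[s], db, strain_id=s, params=GENE_PARAMS)
                    for s in genomes]
        profiles_to_table(profiles).to_csv(
            os.path.join(out, "wgmlst_profiles.tsv"), sep="\t", index_label="strain")
        pdist = profile_distance_matrix(profiles)
        pdist.to_tsv(os.path.join(out, "wgmlst_distances.tsv"))
        tree = upgma(pdist)
        _write(os.path.join(out, "wgmlst_tree.nwk"), tree.to_newick() + "\n")
        artifacts += ["wgmlst_profiles.tsv", "wgmlst_distances.tsv", "wgmlst_tree.nwk"]
        report["wgmlst"] = {"n_loci": len(db), "tree": tree.to_newick()}
        stage_done("wgmlst", loci=len(db))

    # --- pangenome --------------------------------------------------------
    if proteins is not None:
        graph = build_graph(proteins, min_identity=config.pangenome_min_identity,
                            min_coverage=config.pangenome_min_coverage)
        families = mcl(graph, inflation=config.inflation)
        families.to_table().to_csv(os.path.join(out, "pangenome_families.tsv"),
                                   sep="\t", index=False)
        presence = families.presence()
        presence.astype(int).to_csv(os.path.join(out, "pangenome_presence.tsv"),
                                    sep="\t", index_label="strain")
        parts = subsets(families)
        _write(os.path.join(out, "pangenome_subsets.json"),
               json.dumps(parts.to_dict(), indent=2))
        artifacts += ["pangenome_families.tsv", "pangenome_presence.tsv",
                      "pangenome_subsets.json"]
        report["pangenome"] = parts.to_dict()
        stage_done("pangenome", families=families.n_families)

        # --- development curves, fits, support ----------------------------
        hseed = config.stage_seed("heaps")
        curves = {stat: permute_accumulate(presence, stat, config.n_perms, hseed)
                  for stat in ("pangenome", "core", "new_genes")}
        pd.concat([c.to_table() for c in curves.values()]).to_csv(
            os.path.join(out, "heaps_curves.tsv"), sep="\t", index=False)
        fits = {
            "heaps": fit_heaps(curves["pangenome"]).to_dict(),
            "core_decay": fit_decay(curves["core"]).to_dict(),
            "new_genes_decay": fit_decay(curves["new_genes"]).to_dict(),
        }
        _write(os.path.join(out, "heaps_fits.json"), json.dumps(fits, indent=2))
        support = species_support(assignment, ani, presence,
                                  n_perms=config.n_perms, seed=hseed,
                                  ani_cutoff=config.ani.cutoff,
                                  margin=config.support_margin)
        _write(os.path.join(out, "species_support.json"), support.to_json())
        artifacts += ["heaps_curves.tsv", "heaps_fits.json", "species_support.json"]
        report["heaps"] = fits
        report["species_support"] = support.to_dict()
        stage_done("heaps")

    manifest = {name: _sha256(os.path.join(out, name)) for name in artifacts}
    _write(os.path.join(out, "manifest.json"), json.dumps(manifest, indent=2))
    _write(os.path.join(out, "config.json"), config.to_json())
    _write(os.path.join(out, "report.json"), json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# fixtures demo: the stages computable from the printed tables alone
# ---------------------------------------------------------------------------

def fixtures_demo(cutoff: float = 94.0) -> dict:
    """Run the printed-table stages: cohort summary, ANI clustering at the
    cutoff, per-cluster CDS means and ANI extrema."""
    table1 = load_table1()
    stats = cohort_summary(table1)
    ani = load_table2_ani()
    assignment = single_linkage_clusters(ani, cutoff)

    cds = dict(zip(table1["strain_id"], table1["n_cds"]))
    cluster_cds_means = {
        label: round_half_up(float(np.mean([cds[m] for m in members])), 2)
        for label, members in assignment.labels.items()
    }
    off = ani.off_diagonal()
    return {
        "length_range": stats.length_range,
        "gc_min": stats.gc_min,
        "gc_max": stats.gc_max,
        "cds_min": stats.cds_min,
        "cds_max": stats.cds_max,
        "cds_mean": stats.cds_mean,
        "clusters": assignment.to_dict(),
        "cluster_sizes": assignment.sizes(),
        "cluster_cds_means": cluster_cds_means,
        "ani_offdiag_max": float(np.max(off)),
        "ani_offdiag_min": float(np.min(off)),
    }
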