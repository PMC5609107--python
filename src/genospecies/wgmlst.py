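"""Pan-locus allele database, allele calling and UPGMA dendrograms.

The locus database is built greedily over all genes in decreasing length
order: a gene joins the first existing locus whose representative it matches
at >= 90% identity over >= 80% of the representative, otherwise it founds a
new locus.  Allele numbers are the 1-based order of first observation of each
distinct sequence within a locus.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, build_kmer_index, local_align
from .core_io import LabeledMatrix, TreeNode

#: engine defaults for gene-vs-gene comparison; the low exact_threshold keeps
#: everything on the deterministic seeded gapless route
GENE_PARAMS = AlignParams(kmer_size=11, exact_threshold=11)

MISSING = None


@dataclass
class Locus:
    locus_id: str
    representative: str
    alleles: list[str] = field(default_factory=list)  # index+1 = allele number

    def allele_number(self, sequence: str, *, mint: bool = True) -> int | None:
        try:
            return self.alleles.index(sequence) + 1
        except ValueError:
            if not mint:
                return None
            self.alleles.append(sequence)
            return len(self.alleles)


@dataclass
class LocusDB:
    loci: list[Locus]
    min_identity: float = 90.0
    min_coverage: float = 80.0

    def __len__(self):
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]


@dataclass
class AlleleProfile:
    strain_id: str
    calls: dict[str, int | None]  # locus_id -> allele number or MISSING


def _shared_kmer_candidates(seq: str, k: int, index: dict[str, set[int]]) -> set[int]:
    out: set[int] = set()
    for i in range(len(seq) - k + 1):
        hit = index.get(seq[i : i + k])
        if hit:
            out |= hit
    return out


def build_locus_db(cds_sets: dict[str, dict[str, str]],
                   params: AlignParams = GENE_PARAMS,
                   min_identity: float = 90.0,
                   min_coverage: float = 80.0) -> LocusDB:
    """Greedy locus clustering of all genes across the cohort.

    Genes are processed in decreasing length order (ties by strain then gene
    id), making the construction deterministic.
    """
    genes = [(strain, gid, seq)
             for strain, gset in cds_sets.items() for gid, seq in gset.items()]
    if not genes:
        raise ValueError("no genes supplied")
    genes.sort(key=lambda t: (-len(t[2]), t[0], t[1]))

    loci: list[Locus] = []
    kmer_to_locus: dict[str, set[int]] = {}
    k = params.kmer_size

    for strain, gid, seq in genes:
        candidates = sorted(_shared_kmer_candidates(seq, k, kmer_to_locus)) if len(seq) >= k else []
        joined = None
        for li in candidates:
            locus = loci[li]
            hit = local_align(locus.representative, seq, params)
            if (hit is not None and hit.identity >= min_identity
                    and hit.query_cov >= min_coverage):
                locus.allele_number(seq)
                joined = locus
                break
        if joined is None:
            locus = Locus(locus_id=f"L{len(loci) + 1:05d}", representative=seq,
                          alleles=[seq])
            loci.append(locus)
            if len(seq) >= k:
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" not in kmer:
                        kmer_to_locus.setdefault(kmer, set()).add(len(loci) - 1)
    return LocusDB(loci=loci, min_identity=min_identity, min_coverage=min_coverage)


def call_alleles(genome_cds: dict[str, str], db: LocusDB, *,
                 strain_id: str = "strain",
                 params: AlignParams = GENE_PARAMS) -> AlleleProfile:
    """Call one strain's allele profile against the database.

    Per locus the best-scoring gene is taken; the call stands only if it
    reaches ``db.min_identity`` identity and covers at least
    ``db.min_coverage`` percent of the locus representative.  An exact match
    to a registered allele reuses its number; a novel qualifying sequence is
    minted as a new allele (so two strains with the same variant share a
    number).  No qualifying hit leaves the locus MISSING.
    """
    if not db.loci:
        raise ValueError("empty locus database")
    k = params.kmer_size
    gene_ids = sorted(genome_cds)
    kmer_to_gene: dict[str, set[int]] = {}
    for gi, gid in enumerate(gene_ids):
        seq = genome_cds[gid]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                kmer_to_gene.setdefault(kmer, set()).add(gi)

    calls: dict[str, int | None] = {}
    for locus in db.loci:
        rep = locus.representative
        best = None
        best_gene = None
        for gi in sorted(_shared_kmer_candidates(rep, k, kmer_to_gene)):
            seq = genome_cds[gene_ids[gi]]
            hit = local_align(rep, seq, params)
            if hit is None:
                continue
            if best is None or hit.score > best.score:
                best = hit
                best_gene = gene_ids[gi]
        if (best is not None and best.identity >= db.min_identity
                and best.query_cov >= db.min_coverage):
            calls[locus.locus_id] = locus.allele_number(genome_cds[best_gene])
        else:
            calls[locus.locus_id] = MISSING
    return AlleleProfile(strain_id=strain_id, calls=calls)


def profile_distance(p: AlleleProfile, q: AlleleProfile) -> float:
    """Fraction of jointly-called loci with different allele numbers.

    Loci missing in either profile are excluded; NaN (with a warning) when no
    locus is called in both.
    """
    if set(p.calls) != set(q.calls):
        raise ValueError("profiles cover different locus sets")
    shared = diff = 0
    for locus, a in p.calls.items():
        b = q.calls[locus]
        if a is MISSING or b is MISSING:
            continue
        shared += 1
        if a != b:
            diff += 1
    if shared == 0:
        warnings.warn(f"no shared loci between {p.strain_id} and {q.strain_id}")
        return math.nan
    return diff / shared


def profile_distance_matrix(profiles: list[AlleleProfile], *,
                            no_shared_value: float = 1.0) -> LabeledMatrix:
    """Pairwise profile distances; pairs with no jointly-called locus get
    ``no_shared_value`` (default 1.0, the maximum)."""
    ids = [p.strain_id for p in profiles]
    n = len(ids)
    values = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d = profile_distance(profiles[i], profiles[j])
                if math.isnan(d):
                    d = no_shared_value
                values[i, j] = values[j, i] = d
    return LabeledMatrix(ids, list(ids), values, unit="distance")


def profiles_to_table(profiles: list[AlleleProfile]):
    import pandas as pd

    loci = list(profiles[0].calls)
    data = {p.strain_id: ["-" if p.calls[l] is MISSING else p.calls[l] for l in loci]
            for p in profiles}
    return pd.DataFrame(data, index=loci).T


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dist: LabeledMatrix, *, tol: float = 1e-9) -> TreeNode:
    """Size-weighted (arithmetic mean) agglomerative clustering.

    The output is ultrametric: all root-to-leaf path lengths are equal.  Tied
    merge candidates are resolved by the lexicographically smallest member
    labels.
    """
    if not dist.is_square:
        raise ValueError("UPGMA requires a square matrix")
    if dist.max_asymmetry() > tol:
        raise ValueError("UPGMA requires a symmetric matrix")
    values = dist.values
    if np.any(np.diag(values) != 0) or np.any(values < 0):
        raise ValueError("UPGMA requires non-negative distances with zero diagonal")

    @dataclass
    class _Cluster:
        node: TreeNode
        size: int
        height: float
        key: str  # smallest member label, for tie-breaking

    clusters: dict[int, _Cluster] = {
        i: _Cluster(TreeNode(label=lab), 1, 0.0, lab)
        for i, lab in enumerate(dist.row_labels)
    }
    d = {(i, j): float(values[i, j])
         for i in clusters for j in clusters if i < j}
    next_id = len(clusters)

    while len(clusters) > 1:
        (i, j), dij = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted((clusters[kv[0][0]].key,
                                                 clusters[kv[0][1]].key)))),
        )
        ci, cj = clusters.pop(i), clusters.pop(j)
        height = dij / 2.0
        ci.node.branch_length = height - ci.height
        cj.node.branch_length = height - cj.height
        first, second = sorted((ci, cj), key=lambda c: c.key)
        merged = _Cluster(TreeNode(children=[first.node, second.node]),
                          ci.size + cj.size, height, first.key)
        for k in list(clusters):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(k, next_id), max(k, next_id))] = (
                ci.size * dik + cj.size * djk) / (ci.size + cj.size)
        d.pop((i, j), None)
        clusters[next_id] = merged
        next_id += 1

    root = next(iter(clusters.values())).node
    return root
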