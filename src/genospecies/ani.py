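"""Fragment-based average nucleotide identity and threshold clustering.

Each genome is cut into consecutive non-overlapping pieces (default 1,020 bp);
pieces aligning to the partner genome at >= 70% identity over >= 70% of their
length contribute their identity to the mean, and the two directions are
averaged.  Clusters are the connected components of the "ANI >= cutoff" graph
(single linkage): one qualifying pair suffices to join two groups.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, NT_PARAMS, build_kmer_index, local_align
from .core_io import GenomeRecord, LabeledMatrix


@dataclass(frozen=True)
class AniConfig:
    frag_len: int = 1020
    min_identity: float = 70.0
    min_frag_cov: float = 70.0
    cutoff: float = 94.0

    def __post_init__(self):
        if not 0 < self.cutoff <= 100:
            raise ValueError("cutoff must be in (0, 100]")


def _pieces(genome: GenomeRecord, frag_len: int) -> list[str]:
    pieces = []
    for contig in genome.contigs:
        for start in range(0, len(contig) - frag_len + 1, frag_len):
            pieces.append(contig[start : start + frag_len])
    return pieces


def _one_direction(query: GenomeRecord, subject_joined: str, subject_index,
                   config: AniConfig, params: AlignParams) -> float:
    pieces = _pieces(query, config.frag_len)
    if not pieces:
        raise ValueError(
            f"genome {query.strain_id!r} shorter than frag_len={config.frag_len}")
    kept = []
    for piece in pieces:
        hit = local_align(piece, subject_joined, params, subject_index=subject_index)
        if hit is None:
            continue
        if hit.identity >= config.min_identity and hit.query_cov >= config.min_frag_cov:
            kept.append(hit.identity)
    return float(np.mean(kept)) if kept else math.nan


def ani_pair(a: GenomeRecord, b: GenomeRecord,
             config: AniConfig = AniConfig(),
             params: AlignParams = NT_PARAMS, *, _cache: dict | None = None) -> float:
    """Direction-averaged ANI of two genomes (NaN when no fragment passes the
    identity/coverage filters in either direction)."""
    cache = _cache if _cache is not None else {}

    def entry(g: GenomeRecord):
        if g.strain_id not in cache:
            joined = g.joined(sep_len=params.kmer_size + 5)
            cache[g.strain_id] = (joined, build_kmer_index(joined, params.kmer_size))
        return cache[g.strain_id]

    b_joined, b_index = entry(b)
    a_joined, a_index = entry(a)
    ab = _one_direction(a, b_joined, b_index, config, params)
    ba = _one_direction(b, a_joined, a_index, config, params)
    if math.isnan(ab) and math.isnan(ba):
        return math.nan
    if math.isnan(ab) or math.isnan(ba):
        return ab if math.isnan(ba) else ba
    return (ab + ba) / 2.0


def ani_matrix(cohort: dict[str, GenomeRecord],
               config: AniConfig = AniConfig(),
               params: AlignParams = NT_PARAMS) -> LabeledMatrix:
    """Symmetric ANI matrix with a 100 diagonal; missing pairs are NaN."""
    ids = list(cohort)
    if len(ids) < 2:
        raise ValueError("ANI matrix requires at least two genomes")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids")
    cache: dict = {}
    values = np.full((len(ids), len(ids)), 100.0)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            v = ani_pair(cohort[a], cohort[ids[j]], config, params, _cache=cache)
            values[i, j] = values[j, i] = v
    return LabeledMatrix(ids, list(ids), values, unit="percent")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Strain clusters (size >= 2, labelled A, B, C, ... by decreasing size
    then lexicographic smallest member) plus singleton strains."""

    clusters: list[frozenset]
    singletons: frozenset
    cutoff: float
    labels: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if not self.labels:
            self.labels = {_cluster_label(i): c for i, c in enumerate(self.clusters)}

    def cluster_of(self, strain: str) -> str:
        for label, members in self.labels.items():
            if strain in members:
                return label
        if strain in self.singletons:
            return "singleton"
        raise KeyError(strain)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "clusters": {label: sorted(members) for label, members in self.labels.items()},
            "singletons": sorted(self.singletons),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, data: dict) -> "ClusterAssignment":
        clusters = [frozenset(v) for _, v in sorted(data["clusters"].items())]
        return cls(clusters=clusters, singletons=frozenset(data["singletons"]),
                   cutoff=float(data["cutoff"]))


def _cluster_label(i: int) -> str:
    label = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def single_linkage_clusters(matrix: LabeledMatrix, cutoff: float) -> ClusterAssignment:
    """Connected components of the graph with edges where value >= cutoff.

    Accepts slightly asymmetric matrices (as printed tables sometimes are):
    an edge exists if either direction reaches the cutoff.  NaN entries never
    form edges.  Components of size 1 are singletons.
    """
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    if not matrix.is_square:
        raise ValueError("clustering requires a square matrix")
    ids = matrix.row_labels
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vals = matrix.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = [v for v in (vals[i, j], vals[j, i]) if not math.isnan(v)]
            if both and max(both) >= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: dict[int, set[str]] = {}
    for i, sid in enumerate(ids):
        groups.setdefault(find(i), set()).add(sid)
    clusters = sorted((frozenset(g) for g in groups.values() if len(g) >= 2),
                      key=lambda c: (-len(c), min(c)))
    singletons = frozenset(s for g in groups.values() if len(g) == 1 for s in g)
    return ClusterAssignment(clusters=clusters, singletons=singletons, cutoff=cutoff)


def complete_linkage_clusters(matrix: LabeledMatrix, cutoff: float) -> ClusterAssignment:
    """Alternative grouping requiring every within-cluster pair to reach the
    cutoff (scipy complete-linkage cut at 100 - cutoff)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    sym = matrix.symmetrized("mean").values
    dist = 100.0 - sym
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=100.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="complete"),
                      t=100.0 - cutoff, criterion="distance")
    groups: dict[int, set[str]] = {}
    for sid, lab in zip(matrix.row_labels, labels):
        groups.setdefault(int(lab), set()).add(sid)
    clusters = sorted((frozenset(g) for g in groups.values() if len(g) >= 2),
                      key=lambda c: (-len(c), min(c)))
    singletons = frozenset(s for g in groups.values() if len(g) == 1 for s in g)
    return ClusterAssignment(clusters=clusters, singletons=singletons, cutoff=cutoff)
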