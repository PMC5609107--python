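"""Kimura 2-parameter distances on aligned marker genes and a
neighbor-joining tree.

Complete deletion is applied matrix-wide: any column holding a gap or N in
any sequence is removed for every pair before distances are computed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import LabeledMatrix, TreeNode

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistanceError(ValueError):
    """K2P distance undefined: substitution proportions exceed the log domain."""


@dataclass
class AlignedMarkerSet:
    labels: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must all have the same length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        self.sequences = [s.upper() for s in self.sequences]

    def complete_deletion(self) -> "AlignedMarkerSet":
        """Drop every column containing a gap or N in any sequence."""
        arr = np.array([list(s) for s in self.sequences])
        keep = ~np.any((arr == "-") | (arr == "N"), axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        return AlignedMarkerSet(list(self.labels),
                                ["".join(row) for row in arr[:, keep]])


@dataclass
class K2PDistance:
    p: float           # transition proportion
    q: float           # transversion proportion
    d: float
    sites_used: int


def k2p_pair(a: str, b: str) -> K2PDistance:
    """K2P distance of one aligned pair.

    Columns where either sequence holds ``-`` or ``N`` are excluded; P counts
    transitions (A<->G, C<->T) and Q transversions, and
    ``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))``.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be of equal length")
    sites = transitions = transversions = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no usable sites after gap/N exclusion")
    p = transitions / sites
    q = transversions / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(
            f"saturated marker pair (P={p:.4f}, Q={q:.4f})")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PDistance(p=p, q=q, d=d, sites_used=sites)


def k2p_matrix(markers: AlignedMarkerSet) -> LabeledMatrix:
    """Pairwise K2P distances after matrix-wide complete deletion."""
    reduced = markers.complete_deletion()
    n = len(reduced.labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_pair(reduced.sequences[i], reduced.sequences[j]).d
            values[i, j] = values[j, i] = d
    return LabeledMatrix(list(reduced.labels), list(reduced.labels), values,
                         unit="distance")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: LabeledMatrix, *, tol: float = 1e-9) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Returns a tree with a trifurcating root (the standard unrooted NJ shape).
    Negative branch lengths are clamped to 0 with a warning; tied Q values
    are resolved by the lexicographically smallest member labels.
    """
    if not dist.is_square:
        raise ValueError("NJ requires a square matrix")
    if dist.max_asymmetry() > tol:
        raise ValueError("NJ requires a symmetric matrix")
    n = len(dist.row_labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")

    nodes: dict[int, TreeNode] = {i: TreeNode(label=lab)
                                  for i, lab in enumerate(dist.row_labels)}
    keys: dict[int, str] = {i: lab for i, lab in enumerate(dist.row_labels)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))

    def D(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    def clamp(x: float) -> float:
        if x < 0:
            if x < -tol:
                warnings.warn(f"clamping negative NJ branch length {x:.4g} to 0")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        best_key = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                qv = (m - 2) * D(i, j) - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                if best_key is None or (qv, tie) < best_key:
                    best_key = (qv, tie)
                    best = (i, j)
        i, j = best
        dij = D(i, j)
        bi = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        bj = clamp(0.5 * dij + (r[j] - r[i]) / (2.0 * (m - 2)))
        ni, nj_ = nodes.pop(i), nodes.pop(j)
        ni.branch_length, nj_.branch_length = bi, bj
        first, second = sorted(((keys[i], ni), (keys[j], nj_)), key=lambda t: t[0])
        new = TreeNode(children=[first[1], second[1]])
        for k in sorted(active):
            if k in (i, j):
                continue
            dnew = 0.5 * (D(i, k) + D(j, k) - dij)
            d[(min(k, next_id), max(k, next_id))] = dnew
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        nodes[next_id] = new
        keys[next_id] = first[0]
        next_id += 1

    i, j, k = sorted(active, key=lambda x: keys[x])
    bi = clamp(0.5 * (D(i, j) + D(i, k) - D(j, k)))
    bj = clamp(0.5 * (D(i, j) + D(j, k) - D(i, k)))
    bk = clamp(0.5 * (D(i, k) + D(j, k) - D(i, j)))
    nodes[i].branch_length = bi
    nodes[j].branch_length = bj
    nodes[k].branch_length = bk
    children = sorted(((keys[x], nodes[x]) for x in (i, j, k)), key=lambda t: t[0])
    return TreeNode(children=[c for _, c in children])
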