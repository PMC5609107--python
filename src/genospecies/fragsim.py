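"""Fragmented all-vs-all genome similarity.

Each genome is cut into short overlapping windows; every window is searched
against the other genome and the best local-alignment scores are summed and
normalized by the genome's self-score, so self-similarity is exactly 100 and
windows with no hit pull the value down hard.  The resulting percent matrix
is deliberately a much broader-range statistic than ANI (inter-species values
land far below the ANI scale).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignParams, NT_PARAMS, build_kmer_index, local_align
from .core_io import GenomeRecord, LabeledMatrix


@dataclass(frozen=True)
class FragmentationScheme:
    frag_len: int = 200
    step: int = 100
    min_tail: int = 100

    def __post_init__(self):
        if not 0 < self.step <= self.frag_len:
            raise ValueError("require 0 < step <= frag_len")
        if self.min_tail <= 0:
            raise ValueError("min_tail must be positive")


def fragment_genome(genome: GenomeRecord, scheme: FragmentationScheme = FragmentationScheme()) -> list[str]:
    """Ordered fragments, never spanning contigs.

    Contigs of at least ``frag_len`` yield full-length windows starting at
    0, step, 2*step, ...; a contig shorter than ``frag_len`` yields its whole
    sequence as a single fragment when it is at least ``min_tail`` long.
    """
    fragments: list[str] = []
    for contig in genome.contigs:
        L = len(contig)
        if L < scheme.frag_len:
            if L >= scheme.min_tail:
                fragments.append(contig)
            continue
        last_start = (L - scheme.frag_len) // scheme.step * scheme.step
        for start in range(0, last_start + 1, scheme.step):
            fragments.append(contig[start : start + scheme.frag_len])
    return fragments


def _sum_best_scores(fragments: list[str], subject: str,
                     subject_index, params: AlignParams) -> float:
    total = 0.0
    for frag in fragments:
        hit = local_align(frag, subject, params, subject_index=subject_index)
        if hit is not None:
            total += hit.score
    return total


def pair_similarity(a: GenomeRecord, b: GenomeRecord,
                    scheme: FragmentationScheme = FragmentationScheme(),
                    params: AlignParams = NT_PARAMS, *,
                    _cache: dict | None = None) -> float:
    """Percent similarity of ``a`` against ``b``:
    ``100 * sum_f best(f, b) / sum_f best(f, a)`` over a's fragments.
    """
    cache = _cache if _cache is not None else {}
    frags, self_score, _ = _genome_entry(a, scheme, params, cache)
    _, _, b_index = _genome_entry(b, scheme, params, cache)
    if a.strain_id == b.strain_id:
        return 100.0
    score = _sum_best_scores(frags, cache[b.strain_id + "/joined"], b_index, params)
    return 100.0 * score / self_score


def _genome_entry(genome: GenomeRecord, scheme, params, cache):
    key = genome.strain_id
    if key not in cache:
        joined = genome.joined(sep_len=params.kmer_size + 5)
        index = build_kmer_index(joined, params.kmer_size)
        frags = fragment_genome(genome, scheme)
        self_score = _sum_best_scores(frags, joined, index, params)
        if self_score <= 0:
            raise ValueError(f"degenerate genome {key!r}: zero self-score")
        cache[key] = (frags, self_score, index)
        cache[key + "/joined"] = joined
    return cache[key]


def similarity_matrix(cohort: dict[str, GenomeRecord],
                      scheme: FragmentationScheme = FragmentationScheme(),
                      params: AlignParams = NT_PARAMS) -> LabeledMatrix:
    """Asymmetric percent-similarity matrix over all ordered genome pairs.

    value(A, B) is A-as-query vs B-as-subject; the diagonal is exactly 100.
    """
    ids = list(cohort)
    if len(ids) < 2:
        raise ValueError("similarity matrix requires at least two genomes")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids")
    cache: dict = {}
    values = np.full((len(ids), len(ids)), 100.0)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                values[i, j] = pair_similarity(cohort[a], cohort[b], scheme,
                                               params, _cache=cache)
    return LabeledMatrix(ids, list(ids), values, unit="percent")


def distance_matrix(similarity: LabeledMatrix) -> LabeledMatrix:
    """Symmetric companion distance matrix: ``100 - (S + S^T) / 2``."""
    if not similarity.is_square:
        raise ValueError("similarity matrix must be square")
    sym = (similarity.values + similarity.values.T) / 2.0
    values = 100.0 - sym
    np.fill_diagonal(values, 0.0)
    return LabeledMatrix(list(similarity.row_labels), list(similarity.col_labels),
                         values, unit="distance")
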