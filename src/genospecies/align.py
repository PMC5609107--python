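"""Pairwise local-alignment primitive shared by all comparison stages.

Two routes:

* inputs at or below ``exact_threshold`` are aligned with a full
  Smith-Waterman (affine gaps, via Biopython's ``PairwiseAligner`` C kernel);
* longer inputs use a k-mer seeded, per-diagonal gapless extension.  The best
  gapless local alignment on a diagonal is the maximum-sum subarray of the
  +match/-mismatch profile, computed exactly with vectorized prefix sums, so
  the seeded route is deterministic and never overshoots the SW optimum.

Nucleotide searches consider both strands of the query.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    kmer_size: int = 11
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    exact_threshold: int = 400

    def __post_init__(self):
        if self.kmer_size < 2:
            raise ValueError("kmer_size must be >= 2")
        if self.exact_threshold < self.kmer_size:
            raise ValueError("exact_threshold must be >= kmer_size")


#: nucleotide defaults
NT_PARAMS = AlignParams()
#: protein defaults: short seeds, no strand search; exact route rarely needed
AA_PARAMS = AlignParams(kmer_size=4, exact_threshold=4)


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    identity: float      # percent identical columns over the alignment
    aln_len: int         # alignment columns (including gap columns)
    query_cov: float     # percent of the query spanned by the alignment
    subject_cov: float   # percent of the subject spanned by the alignment
    score: float
    strand: str = "+"
    q_start: int = 0     # 0-based half-open, on the aligned strand
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0


def build_kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    """Map every k-mer of ``sequence`` to its start positions; k-mers
    containing ``N`` are omitted."""
    if k > len(sequence):
        raise ValueError(f"k={k} exceeds sequence length {len(sequence)}")
    index: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _exact_hit(query: str, subject: str, params: AlignParams,
               query_id: str, subject_id: str) -> LocalHit | None:
    aligner = _aligner(params)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    q_segments, s_segments = aln.aligned
    q_start, q_end = int(q_segments[0][0]), int(q_segments[-1][1])
    s_start, s_end = int(s_segments[0][0]), int(s_segments[-1][1])
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=100.0 * counts.identities / aln_len,
        aln_len=int(aln_len),
        query_cov=100.0 * (q_end - q_start) / len(query),
        subject_cov=100.0 * (s_end - s_start) / len(subject),
        score=float(score),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N_BYTE = ord("N")


def _best_on_diagonal(qa: np.ndarray, sa: np.ndarray, offset: int,
                      params: AlignParams, *, n_is_wildcard: bool):
    """Exact best gapless local alignment on one diagonal.

    Returns ``(score, q_start, q_end, matches)`` or ``None``.  The diagonal is
    the set of pairs (i, i + offset); Kadane's maximum-sum subarray is solved
    with prefix sums and running minima so the whole diagonal is one numpy op.
    With ``n_is_wildcard`` (nucleotide mode) N never counts as a match; in
    amino-acid mode N is asparagine and compares normally.
    """
    q0 = max(0, -offset)
    q1 = min(len(qa), len(sa) - offset)
    if q1 - q0 < 1:
        return None
    q = qa[q0:q1]
    s = sa[q0 + offset : q1 + offset]
    eq = q == s
    if n_is_wildcard:
        eq &= q != _N_BYTE
    vals = np.where(eq, params.match, params.mismatch).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(vals)))
    running_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - running_min
    j = int(np.argmax(gains))
    score = int(gains[j])
    if score <= 0:
        return None
    # recover the start: last index <= j where the prefix equals the running min
    idx = np.arange(j + 1)
    at_min = prefix[: j + 1] == running_min[j]
    start = int(idx[at_min][-1])
    end = j + 1
    matches = int(np.count_nonzero(eq[start:end]))
    return score, q0 + start, q0 + end, matches


def _seeded_hit(query: str, subject: str, params: AlignParams,
                query_id: str, subject_id: str,
                subject_index: dict[str, list[int]] | None,
                n_is_wildcard: bool = True) -> LocalHit | None:
    k = params.kmer_size
    if len(query) < k or len(subject) < k:
        return None
    if subject_index is None:
        subject_index = build_kmer_index(subject, k)
    offsets: set[int] = set()
    for i in range(len(query) - k + 1):
        positions = subject_index.get(query[i : i + k])
        if positions:
            for pos in positions:
                offsets.add(pos - i)
    if not offsets:
        return None
    qa = _encode(query)
    sa = _encode(subject)
    best = None
    best_key = None
    for offset in sorted(offsets):
        res = _best_on_diagonal(qa, sa, offset, params,
                                n_is_wildcard=n_is_wildcard)
        if res is None:
            continue
        score, q_start, q_end, matches = res
        key = (-score, q_start, q_start + offset)
        if best_key is None or key < best_key:
            best_key = key
            best = (score, q_start, q_end, offset, matches)
    if best is None:
        return None
    score, q_start, q_end, offset, matches = best
    length = q_end - q_start
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=100.0 * matches / length,
        aln_len=length,
        query_cov=100.0 * length / len(query),
        subject_cov=100.0 * length / len(subject),
        score=float(score),
        q_start=q_start,
        q_end=q_end,
        s_start=q_start + offset,
        s_end=q_end + offset,
    )


def local_align(query: str, subject: str, params: AlignParams = NT_PARAMS, *,
                mode: str = "nt", query_id: str = "query",
                subject_id: str = "subject",
                subject_index: dict[str, list[int]] | None = None) -> LocalHit | None:
    """Best local alignment of ``query`` against ``subject`` (or ``None``).

    Nucleotide mode searches both query strands and reports the better one
    (``+`` preferred on ties).  ``subject_index`` may carry a pre-built k-mer
    index of the subject to amortize repeated searches.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    exact = (len(query) <= params.exact_threshold
             and len(subject) <= params.exact_threshold)

    def one_strand(q: str) -> LocalHit | None:
        if exact:
            return _exact_hit(q, subject, params, query_id, subject_id)
        return _seeded_hit(q, subject, params, query_id, subject_id,
                           subject_index, n_is_wildcard=(mode == "nt"))

    fwd = one_strand(query)
    if mode != "nt":
        return fwd
    rev = one_strand(revcomp(query))
    if rev is not None and (fwd is None or rev.score > fwd.score):
        return replace(rev, strand="-")
    return fwd


def best_hit(query: str, subjects, params: AlignParams = NT_PARAMS, *,
             mode: str = "nt", query_id: str = "query",
             subject_indexes: dict | None = None) -> LocalHit | None:
    """Best hit of ``query`` over a collection of subjects.

    ``subjects`` is a mapping ``subject_id -> sequence``.  Ties on score are
    broken by lexicographic subject id (subjects are scanned in sorted order
    and only a strictly better score displaces the incumbent).
    """
    if not subjects:
        raise ValueError("at least one subject is required")
    best = None
    for sid in sorted(subjects):
        idx = subject_indexes.get(sid) if subject_indexes else None
        hit = local_align(query, subjects[sid], params, mode=mode,
                          query_id=query_id, subject_id=sid, subject_index=idx)
        if hit is not None and (best is None or hit.score > best.score):
            best = hit
    return best
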