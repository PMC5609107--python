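"""Independent brute-force oracles used by the tests.

These deliberately re-derive results through a different route than the
package (plain-Python DP, naive scans, direct counting) so that agreement is
meaningful.
"""
from __future__ import annotations


def sw_score(q: str, s: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> int:
    """Full Gotoh local-alignment score; the opening gap position costs
    ``gap_open`` and each further position ``gap_extend``."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume s)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (consume q)
    best = 0.0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + (match if qi == s[j - 1] else mismatch)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def naive_kmer_positions(seq: str, kmer: str) -> list[int]:
    k = len(kmer)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer]


def gc_percent(seq: str) -> float:
    gc = sum(1 for c in seq if c in "GC")
    acgt = sum(1 for c in seq if c in "ACGT")
    return 100.0 * gc / acgt


def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def k2p_site_classes(a: str, b: str):
    """Count (used, transitions, transversions) with per-pair gap exclusion."""
    purines = {"A", "G"}
    used = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        used += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    return used, ts, tv
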