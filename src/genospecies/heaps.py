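"""Permutation-based pangenome development curves, Heap's-law and
exponential-decay fits, and the joint ANI + alpha species-support decision.

The pangenome growth exponent gamma is the slope of log(median curve) on
log(N); alpha = 1 - gamma, and alpha <= 1 classifies the pangenome as open.
Core and new-gene curves are extrapolated with a least-squares fit of
``n(x) = k * exp(-x / t) + tg_theta`` to the per-N means, whose asymptote
``tg_theta`` is the convergence value.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .ani import ClusterAssignment
from .core_io import LabeledMatrix

STATISTICS = ("pangenome", "core", "new_genes")


@dataclass
class DevelopmentCurve:
    statistic: str
    n_values: np.ndarray          # genome counts 1..G
    samples: np.ndarray           # (n_perms, G) values
    n_perms: int
    seed: int
    exhaustive: bool

    @property
    def medians(self) -> np.ndarray:
        return np.median(self.samples, axis=0)

    @property
    def means(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def to_table(self) -> pd.DataFrame:
        rows = [
            (self.statistic, int(n), p, int(self.samples[p, i]))
            for p in range(self.samples.shape[0])
            for i, n in enumerate(self.n_values)
        ]
        return pd.DataFrame(rows, columns=["statistic", "N", "perm_index", "value"])


def permute_accumulate(presence: pd.DataFrame, statistic: str,
                       n_perms: int = 100, seed: int = 0) -> DevelopmentCurve:
    """Accumulation curve of a statistic over permutations of genome order.

    ``presence`` is a boolean genomes x families matrix.  For each genome
    prefix of length N: *pangenome* counts families present in any prefix
    genome, *core* counts families present in all of them, and *new_genes*
    counts families present in genome N but in no earlier genome.  All G!
    orders are enumerated exhaustively when G! <= n_perms; otherwise
    ``n_perms`` random orders are drawn from the seeded generator.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    mat = presence.to_numpy(dtype=bool)
    g = mat.shape[0]
    if g < 2:
        raise ValueError("at least two genomes are required")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")

    exhaustive = math.factorial(g) <= n_perms
    if exhaustive:
        orders = [np.array(p) for p in permutations(range(g))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(g) for _ in range(n_perms)]

    samples = np.empty((len(orders), g), dtype=np.int64)
    for pi, order in enumerate(orders):
        sub = mat[order]
        if statistic == "pangenome":
            samples[pi] = np.logical_or.accumulate(sub, axis=0).sum(axis=1)
        elif statistic == "core":
            samples[pi] = np.logical_and.accumulate(sub, axis=0).sum(axis=1)
        else:  # new_genes
            cum = np.logical_or.accumulate(sub, axis=0).sum(axis=1)
            samples[pi, 0] = cum[0]
            samples[pi, 1:] = np.diff(cum)
    return DevelopmentCurve(statistic=statistic, n_values=np.arange(1, g + 1),
                            samples=samples, n_perms=len(orders), seed=seed,
                            exhaustive=exhaustive)


@dataclass
class HeapsFit:
    k: float
    gamma: float
    alpha: float
    r2: float
    open: bool

    def to_dict(self) -> dict:
        return {"k": self.k, "gamma": self.gamma, "alpha": self.alpha,
                "r2": self.r2, "open": self.open}


def fit_heaps(curve: DevelopmentCurve, *, include_n1: bool = True) -> HeapsFit:
    """Power-law fit of the pangenome medians: OLS of log(median) on log(N).

    gamma is the slope, k = exp(intercept) and alpha = 1 - gamma; alpha <= 1
    classifies the pangenome as open.
    """
    n = curve.n_values.astype(float)
    y = curve.medians.astype(float)
    if not include_n1:
        mask = n >= 2
        n, y = n[mask], y[mask]
    if np.any(y <= 0):
        raise ValueError("medians must be positive for a log-log fit")
    if len(np.unique(n)) < 3:
        raise ValueError("need at least 3 distinct N values")
    res = linregress(np.log(n), np.log(y))
    gamma = float(res.slope)
    alpha = 1.0 - gamma
    r2 = float(res.rvalue ** 2) if not math.isnan(res.rvalue) else 1.0
    return HeapsFit(k=float(math.exp(res.intercept)), gamma=gamma, alpha=alpha,
                    r2=r2, open=alpha <= 1.0)


@dataclass
class DecayFit:
    k: float
    t: float
    tg_theta: float
    rss: float

    def predict(self, x) -> np.ndarray:
        return self.k * np.exp(-np.asarray(x, dtype=float) / self.t) + self.tg_theta

    def to_dict(self) -> dict:
        return {"k": self.k, "t": self.t, "tg_theta": self.tg_theta, "rss": self.rss}


def fit_decay(curve: DevelopmentCurve) -> DecayFit:
    """Exponential-decay fit ``n(x) = k*exp(-x/t) + tg_theta`` to the per-N
    means.

    The model is linear in (k, tg_theta) for fixed t, so t is profiled over a
    dense multiplicative grid with exact linear least squares at each point
    (respecting tg_theta >= 0); the best grid solution seeds a ``curve_fit``
    polish.  This is equivalent to a very generous multi-start and cannot
    fail to return a fit.
    """
    x = curve.n_values.astype(float)
    y = curve.means.astype(float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct N values")

    def model(xv, k, t, tg):
        return k * np.exp(-xv / t) + tg

    def profile(t: float):
        basis = np.exp(-x / t)
        A = np.column_stack([basis, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        k, tg = float(coef[0]), float(coef[1])
        if tg < 0:  # clamp the asymptote and refit the scale alone
            tg = 0.0
            denom = float(basis @ basis)
            k = float(basis @ y) / denom if denom > 0 else 0.0
        rss = float(np.sum((k * basis + tg - y) ** 2))
        return DecayFit(k=k, t=float(t), tg_theta=tg, rss=rss)

    grid = np.geomspace(0.05, 10.0 * x[-1], 200)
    best = min((profile(t) for t in grid), key=lambda f: f.rss)
    try:
        popt, _ = curve_fit(
            model, x, y, p0=(best.k if best.k != 0 else 1.0, best.t,
                             best.tg_theta),
            bounds=([-np.inf, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if rss <= best.rss:
            best = DecayFit(k=float(popt[0]), t=float(popt[1]),
                            tg_theta=float(popt[2]), rss=rss)
    except (RuntimeError, ValueError):
        pass  # keep the profiled grid solution
    return best


# ---------------------------------------------------------------------------
# species support
# ---------------------------------------------------------------------------

@dataclass
class ClusterSupport:
    label: str
    members: list[str]
    alpha: float | None
    min_intra_ani: float | None
    core_fraction: float | None
    verdict: str               # "supported" | "not-supported" | "insufficient"
    reasons: list[str] = field(default_factory=list)


@dataclass
class SpeciesSupport:
    global_alpha: float
    global_core_fraction: float
    ani_cutoff: float
    margin: float
    clusters: list[ClusterSupport]

    def to_dict(self) -> dict:
        return {
            "global_alpha": self.global_alpha,
            "global_core_fraction": self.global_core_fraction,
            "ani_cutoff": self.ani_cutoff,
            "margin": self.margin,
            "clusters": [
                {
                    "label": c.label,
                    "members": c.members,
                    "alpha": c.alpha,
                    "min_intra_ani": c.min_intra_ani,
                    "core_fraction": c.core_fraction,
                    "verdict": c.verdict,
                    "reasons": c.reasons,
                }
                for c in self.clusters
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _alpha_and_core_fraction(presence: pd.DataFrame, n_perms: int, seed: int):
    present = presence.loc[:, presence.any(axis=0)]
    curve = permute_accumulate(present, "pangenome", n_perms=n_perms, seed=seed)
    alpha = fit_heaps(curve).alpha
    core = int(present.all(axis=0).sum())
    return alpha, core / present.shape[1]


def species_support(assignment: ClusterAssignment, ani: LabeledMatrix,
                    presence: pd.DataFrame, n_perms: int = 100, seed: int = 0,
                    ani_cutoff: float | None = None,
                    margin: float = 0.02) -> SpeciesSupport:
    """Joint ANI + pangenome-openness support for each candidate cluster.

    A cluster is *supported* when its alpha exceeds the whole-cohort alpha by
    at least ``margin`` (a cluster of near-clonal genomes accumulates new
    genes more slowly than the cohort) and every intra-cluster ANI value
    reaches the cutoff.  Clusters with fewer than 3 genomes are reported as
    "insufficient".
    """
    if ani_cutoff is None:
        ani_cutoff = assignment.cutoff
    global_alpha, global_core_frac = _alpha_and_core_fraction(presence, n_perms, seed)

    reports: list[ClusterSupport] = []
    for label, members in assignment.labels.items():
        members = sorted(members)
        missing = [m for m in members if m not in presence.index
                   or m not in ani.row_labels]
        if missing:
            raise ValueError(f"cluster {label} members missing from inputs: {missing}")
        if len(members) < 3:
            reports.append(ClusterSupport(label, members, None, None, None,
                                          "insufficient",
                                          ["fewer than 3 genomes"]))
            continue
        idx = [ani.row_labels.index(m) for m in members]
        sub = ani.values[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        min_ani = float(np.nanmin(off)) if not np.all(np.isnan(off)) else math.nan
        alpha, core_frac = _alpha_and_core_fraction(
            presence.loc[members], n_perms, seed)
        reasons = []
        if math.isnan(min_ani) or min_ani < ani_cutoff:
            reasons.append(f"ANI: min intra-cluster ANI {min_ani:.2f} "
                           f"below cutoff {ani_cutoff:.2f}")
        if alpha <= global_alpha + margin:
            reasons.append(f"alpha: cluster alpha {alpha:.3f} does not exceed "
                           f"global alpha {global_alpha:.3f} by margin {margin}")
        verdict = "supported" if not reasons else "not-supported"
        reports.append(ClusterSupport(label, members, alpha, min_ani,
                                      core_frac, verdict, reasons))
    return SpeciesSupport(global_alpha=global_alpha,
                          global_core_fraction=global_core_frac,
                          ani_cutoff=float(ani_cutoff), margin=margin,
                          clusters=reports)
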