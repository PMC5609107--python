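import math

import numpy as np
import pandas as pd
import pytest

from genospecies.ani import single_linkage_clusters
from genospecies.core_io import LabeledMatrix
from genospecies.heaps import (DevelopmentCurve, fit_decay, fit_heaps,
                               permute_accumulate, species_support)


def presence_df(rows, families=None):
    arr = np.array(rows, dtype=bool)
    idx = [f"s{i}" for i in range(arr.shape[0])]
    cols = families or [f"f{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=idx, columns=cols)


def curve_from_values(values, statistic="pangenome"):
    values = np.asarray(values, dtype=float)
    return DevelopmentCurve(statistic=statistic,
                            n_values=np.arange(1, len(values) + 1),
                            samples=values[None, :], n_perms=1, seed=0,
                            exhaustive=True)


# ---------------------------------------------------------------------------
# permutation curves
# ---------------------------------------------------------------------------

def test_identical_genomes_flat_curves():
    p = presence_df([[1, 1, 1], [1, 1, 1]])
    pan = permute_accumulate(p, "pangenome", n_perms=10, seed=0)
    assert np.all(pan.samples == 3)
    new = permute_accumulate(p, "new_genes", n_perms=10, seed=0)
    assert np.all(new.samples[:, 1] == 0)


def test_disjoint_families_exhaustive_means():
    p = presence_df([
        [1, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 1, 1, 1],
    ])
    pan = permute_accumulate(p, "pangenome", n_perms=10, seed=0)
    assert pan.exhaustive and pan.n_perms == 6
    assert pan.means[0] == pytest.approx((2 + 3 + 4) / 3)
    assert pan.means[2] == pytest.approx(9.0)


def test_seed_determinism(rng):
    p = presence_df(rng.random((6, 40)) < 0.5)
    c1 = permute_accumulate(p, "pangenome", n_perms=30, seed=5)
    c2 = permute_accumulate(p, "pangenome", n_perms=30, seed=5)
    np.testing.assert_array_equal(c1.samples, c2.samples)
    c3 = permute_accumulate(p, "pangenome", n_perms=30, seed=6)
    assert not np.array_equal(c1.samples, c3.samples)


def test_curve_monotonicity(rng):
    for _ in range(5):
        p = presence_df(rng.random((7, 50)) < 0.4)
        pan = permute_accumulate(p, "pangenome", n_perms=20, seed=1)
        core = permute_accumulate(p, "core", n_perms=20, seed=1)
        assert np.all(np.diff(np.median(pan.samples, axis=0)) >= 0)
        assert np.all(np.diff(np.median(core.samples, axis=0)) <= 0)
        # per-permutation monotonicity holds as well
        assert np.all(np.diff(pan.samples, axis=1) >= 0)
        assert np.all(np.diff(core.samples, axis=1) <= 0)


def test_new_gene_conservation_exhaustive(rng):
    p = presence_df(rng.random((4, 30)) < 0.5)
    pan = permute_accumulate(p, "pangenome", n_perms=100, seed=0)
    new = permute_accumulate(p, "new_genes", n_perms=100, seed=0)
    assert pan.exhaustive and new.exhaustive
    assert new.means.sum() == pytest.approx(pan.means[-1])


def test_unknown_statistic():
    p = presence_df([[1, 0], [0, 1]])
    with pytest.raises(ValueError, match="statistic"):
        permute_accumulate(p, "bogus")


# ---------------------------------------------------------------------------
# Heap's law fit
# ---------------------------------------------------------------------------

def test_fit_heaps_exact_power_law():
    n = np.arange(1, 11)
    curve = curve_from_values(1000.0 * n ** 0.4)
    fit = fit_heaps(curve)
    assert fit.gamma == pytest.approx(0.400, abs=1e-3)
    assert fit.alpha == pytest.approx(0.600, abs=1e-3)
    assert fit.k == pytest.approx(1000.0, rel=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.open
    assert fit.alpha + fit.gamma == 1.0


def test_fit_heaps_constant_curve():
    fit = fit_heaps(curve_from_values([250.0] * 8))
    assert fit.gamma == pytest.approx(0.0, abs=1e-12)
    assert fit.alpha == 1.0
    assert fit.open  # boundary: alpha <= 1 counts as open


def test_fit_heaps_requires_positive():
    with pytest.raises(ValueError):
        fit_heaps(curve_from_values([0.0, 1.0, 2.0, 3.0]))


def test_fit_heaps_exclude_n1():
    n = np.arange(1, 11).astype(float)
    values = 500.0 * n ** 0.3
    values[0] = 700.0  # distorted N=1 point
    fit = fit_heaps(curve_from_values(values), include_n1=False)
    assert fit.gamma == pytest.approx(0.3, abs=1e-3)


# ---------------------------------------------------------------------------
# decay fit
# ---------------------------------------------------------------------------

def test_fit_decay_exact_exponential():
    x = np.arange(1, 13)
    curve = curve_from_values(200.0 * np.exp(-x / 3.0) + 1400.0, "core")
    fit = fit_decay(curve)
    assert fit.tg_theta == pytest.approx(1400.0, abs=1.0)
    assert fit.t == pytest.approx(3.0, abs=0.05)
    assert fit.k == pytest.approx(200.0, rel=0.02)


def test_fit_decay_constant():
    fit = fit_decay(curve_from_values([1500.0] * 10, "core"))
    assert fit.tg_theta == pytest.approx(1500.0, abs=0.5)
    assert abs(fit.k) < 1.0


def test_fit_decay_needs_points():
    with pytest.raises(ValueError):
        fit_decay(curve_from_values([3.0, 2.0, 1.0], "core"))


def test_fit_recovery_on_simulated_core_curve():
    # loss-free cohort: the core curve converges to the truth core size
    from genospecies.simulate import SimConfig, simulate_cohort
    from genospecies.pangenome import build_graph, mcl

    cfg = SimConfig(n_clusters=1, genomes_per_cluster=(8,), n_singleton_strains=0,
                    core_genes=40, cluster_accessory=0, private_genes_mean=4.0,
                    gene_loss_prob=0.0, seed=17)
    cohort = simulate_cohort(cfg)
    families = mcl(build_graph(cohort.proteins), inflation=1.5)
    presence = families.presence()
    curve = permute_accumulate(presence, "core", n_perms=50, seed=3)
    fit = fit_decay(curve)
    assert fit.tg_theta == pytest.approx(40, rel=0.02)


# ---------------------------------------------------------------------------
# species support
# ---------------------------------------------------------------------------

def _ani_matrix(ids, fill):
    vals = np.full((len(ids), len(ids)), fill)
    np.fill_diagonal(vals, 100.0)
    return LabeledMatrix(ids, list(ids), vals)


def test_clone_split_not_supported(rng):
    ids = [f"s{i}" for i in range(6)]
    presence = pd.DataFrame(np.ones((6, 50), dtype=bool), index=ids,
                            columns=[f"f{j}" for j in range(50)])
    matrix = _ani_matrix(ids, 100.0)
    assignment = single_linkage_clusters(matrix, 94.0)
    # force an arbitrary split of the clones into two "clusters"
    from genospecies.ani import ClusterAssignment
    fake = ClusterAssignment(clusters=[frozenset(ids[:3]), frozenset(ids[3:])],
                             singletons=frozenset(), cutoff=94.0)
    support = species_support(fake, matrix, presence, n_perms=20, seed=0)
    for c in support.clusters:
        assert c.verdict == "not-supported"
        assert any("alpha" in r for r in c.reasons)


def test_low_ani_cluster_flagged():
    ids = ["a", "b", "c"]
    vals = np.array([[100.0, 95.0, 88.0], [95.0, 100.0, 95.0],
                     [88.0, 95.0, 100.0]])
    matrix = LabeledMatrix(ids, list(ids), vals)
    rng = np.random.default_rng(0)
    presence = pd.DataFrame(rng.random((3, 60)) < 0.6, index=ids,
                            columns=[f"f{j}" for j in range(60)])
    from genospecies.ani import ClusterAssignment
    fake = ClusterAssignment(clusters=[frozenset(ids)], singletons=frozenset(),
                             cutoff=94.0)
    support = species_support(fake, matrix, presence, n_perms=20, seed=0,
                              ani_cutoff=94.0)
    (cluster,) = support.clusters
    assert cluster.verdict == "not-supported"
    assert any(r.startswith("ANI") for r in cluster.reasons)


def test_small_cluster_insufficient():
    ids = ["a", "b", "c"]
    matrix = _ani_matrix(ids, 98.0)
    presence = pd.DataFrame(np.ones((3, 10), dtype=bool), index=ids,
                            columns=[f"f{j}" for j in range(10)])
    from genospecies.ani import ClusterAssignment
    fake = ClusterAssignment(clusters=[frozenset(["a", "b"])],
                             singletons=frozenset(["c"]), cutoff=94.0)
    support = species_support(fake, matrix, presence, n_perms=10, seed=0)
    assert support.clusters[0].verdict == "insufficient"


def test_supported_invariant(default_cohort, default_ani, default_assignment,
                             default_families):
    presence = default_families.presence()
    support = species_support(default_assignment, default_ani, presence,
                              n_perms=50, seed=0)
    for c in support.clusters:
        if c.verdict == "supported":
            assert c.alpha > support.global_alpha
            assert c.min_intra_ani >= support.ani_cutoff
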