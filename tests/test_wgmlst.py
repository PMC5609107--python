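import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from genospecies.core_io import LabeledMatrix, leaf_depths, tree_leaf_distances
from genospecies.simulate import SimConfig, simulate_cohort
from genospecies.wgmlst import (GENE_PARAMS, AlleleProfile, build_locus_db,
                                call_alleles, profile_distance,
                                profile_distance_matrix, upgma)


def random_gene(rng, n=300):
    return "ATG" + "".join("ACGT"[b] for b in rng.integers(0, 4, size=n - 6)) + "TAA"


def substituted(seq, n_subs):
    """Deterministically substitute n_subs evenly spaced positions."""
    out = list(seq)
    step = len(seq) // n_subs
    for i in range(n_subs):
        pos = 3 + i * step
        if pos >= len(seq) - 3:
            break
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


# ---------------------------------------------------------------------------
# locus DB
# ---------------------------------------------------------------------------

def test_identical_genes_one_locus(rng):
    gene = random_gene(rng)
    db = build_locus_db({f"s{i}": {"g": gene} for i in range(3)})
    assert len(db) == 1
    assert db.loci[0].alleles == [gene]


def test_divergent_genes_two_loci(rng):
    a = random_gene(rng)
    b = random_gene(rng)  # unrelated, ~25% identity
    db = build_locus_db({"s1": {"g": a}, "s2": {"g": b}})
    assert len(db) == 2


def test_near_identical_genes_share_locus(rng):
    a = random_gene(rng, 300)
    b = substituted(a, 15)  # 95% identity
    db = build_locus_db({"s1": {"g": a}, "s2": {"g": b}})
    assert len(db) == 1
    assert len(db.loci[0].alleles) == 2


def test_locus_count_matches_truth_families():
    cfg = SimConfig(n_clusters=1, genomes_per_cluster=(6,), n_singleton_strains=0,
                    core_genes=30, cluster_accessory=8, private_genes_mean=3.0,
                    seed=13)
    cohort = simulate_cohort(cfg)
    truth_families = {fam for inv in cohort.truth.gene_family.values()
                      for fam in inv.values()}
    db = build_locus_db(cohort.genes)
    assert abs(len(db) - len(truth_families)) <= max(1, 0.02 * len(truth_families))


def test_empty_input_fails():
    with pytest.raises(ValueError):
        build_locus_db({})


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------

def test_call_representatives_all_allele_1(rng):
    genes = {f"g{i}": random_gene(rng) for i in range(5)}
    db = build_locus_db({"ref": genes})
    profile = call_alleles(genes, db, strain_id="ref")
    assert all(v == 1 for v in profile.calls.values())


def test_call_below_identity_missing(rng):
    gene = random_gene(rng, 300)
    db = build_locus_db({"ref": {"g": gene}})
    distant = substituted(gene, 45)  # ~85% identity, below the 90% filter
    profile = call_alleles({"g": distant}, db)
    assert profile.calls[db.loci[0].locus_id] is None


def test_shared_novel_variant_same_number(rng):
    gene = random_gene(rng, 300)
    variant = substituted(gene, 9)  # 97% identity, qualifies as a new allele
    db = build_locus_db({"ref": {"g": gene}})
    p1 = call_alleles({"g": variant}, db, strain_id="s1")
    p2 = call_alleles({"g": variant}, db, strain_id="s2")
    locus = db.loci[0].locus_id
    assert p1.calls[locus] == p2.calls[locus] == 2


def test_self_call_no_missing_loss_free():
    cfg = SimConfig(n_clusters=1, genomes_per_cluster=(4,), n_singleton_strains=0,
                    core_genes=20, cluster_accessory=0, private_genes_mean=0.0,
                    gene_loss_prob=0.0, seed=21)
    cohort = simulate_cohort(cfg)
    db = build_locus_db(cohort.genes)
    for strain in cohort.genomes:
        profile = call_alleles(cohort.genes[strain], db, strain_id=strain)
        assert all(v is not None for v in profile.calls.values()), strain


# ---------------------------------------------------------------------------
# profile distance
# ---------------------------------------------------------------------------

def _profile(sid, calls):
    return AlleleProfile(sid, calls)


def test_profile_distance_identical():
    p = _profile("a", {"l1": 1, "l2": 2})
    assert profile_distance(p, _profile("b", {"l1": 1, "l2": 2})) == 0.0


def test_profile_distance_fraction():
    calls_a = {f"l{i}": 1 for i in range(10)}
    calls_b = dict(calls_a)
    for i in range(4):
        calls_b[f"l{i}"] = 2
    assert profile_distance(_profile("a", calls_a), _profile("b", calls_b)) == 0.4


def test_profile_distance_excludes_missing():
    p = _profile("a", {"l1": 1, "l2": None, "l3": 1})
    q = _profile("b", {"l1": 2, "l2": 5, "l3": 1})
    assert profile_distance(p, q) == 0.5  # l2 excluded


def test_profile_distance_no_shared_nan():
    p = _profile("a", {"l1": 1, "l2": None})
    q = _profile("b", {"l1": None, "l2": 1})
    with pytest.warns(UserWarning, match="no shared loci"):
        assert math.isnan(profile_distance(p, q))


def test_profile_distance_mismatched_loci():
    with pytest.raises(ValueError):
        profile_distance(_profile("a", {"l1": 1}), _profile("b", {"l2": 1}))


def test_profile_distance_pseudometric(rng):
    loci = [f"l{i}" for i in range(20)]
    profiles = [_profile(f"s{i}", {l: int(rng.integers(1, 4)) for l in loci})
                for i in range(6)]
    for p, q in itertools.combinations(profiles, 2):
        assert profile_distance(p, q) == profile_distance(q, p)
        assert profile_distance(p, p) == 0.0
    for p, q, r in itertools.combinations(profiles, 3):
        assert (profile_distance(p, r)
                <= profile_distance(p, q) + profile_distance(q, r) + 1e-12)


def test_cluster_structure_in_profile_distances():
    # allele identity saturates quickly (any base change mints a new allele),
    # so cluster structure in profile space needs strain-level divergence
    cfg = SimConfig(n_clusters=2, genomes_per_cluster=(3, 3),
                    n_singleton_strains=1, core_genes=25, cluster_accessory=5,
                    private_genes_mean=2.0, d_within=0.001, d_between=0.13,
                    seed=19)
    cohort = simulate_cohort(cfg)
    db = build_locus_db(cohort.genes)
    profiles = [call_alleles(cohort.genes[s], db, strain_id=s)
                for s in cohort.genomes]
    dist = profile_distance_matrix(profiles)
    ids = dist.row_labels
    within, between = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        ca = cohort.truth.strain_cluster[ids[i]]
        cb = cohort.truth.strain_cluster[ids[j]]
        (within if ca == cb != "singleton" else between).append(dist.values[i, j])
    assert max(within) < min(between)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_hand_example():
    m = LabeledMatrix(["A", "B", "C"], ["A", "B", "C"],
                      np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]]))
    tree = upgma(m)
    assert tree.to_newick() == "((A:1,B:1):3,C:4);"


def test_upgma_two_taxa():
    m = LabeledMatrix(["A", "B"], ["A", "B"], np.array([[0.0, 6.0], [6.0, 0.0]]))
    assert upgma(m).to_newick() == "(A:3,B:3);"


def test_upgma_ultrametric_output(rng):
    for _ in range(10):
        n = 7
        vals = rng.random((n, n)) * 10
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(LabeledMatrix(labels, list(labels), vals))
        depths = leaf_depths(tree)
        assert max(depths.values()) - min(depths.values()) < 1e-9


def test_upgma_recovers_ultrametric_matrix(rng):
    # build an ultrametric matrix from random agglomeration heights
    n = 8
    labels = [f"t{i}" for i in range(n)]
    heights = np.sort(rng.random(n - 1)) + 0.5
    # agglomerate sequentially: cluster i joins at heights[i-1]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = 2 * heights[max(i, j) - 1]
    m = LabeledMatrix(labels, list(labels), vals)
    tree = upgma(m)
    recovered = tree_leaf_distances(tree)
    for a in labels:
        for b in labels:
            assert recovered.loc(a, b) == pytest.approx(m.loc(a, b), abs=1e-9)


def test_upgma_matches_scipy_cophenetic(rng):
    n = 9
    vals = rng.random((n, n)) * 5
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    labels = [f"t{i}" for i in range(n)]
    tree = upgma(LabeledMatrix(labels, list(labels), vals))
    ours = tree_leaf_distances(tree)
    coph = squareform(cophenet(linkage(squareform(vals, checks=False),
                                       method="average")))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            assert ours.loc(a, b) == pytest.approx(coph[i, j], abs=1e-9)


def test_upgma_rejects_asymmetric():
    m = LabeledMatrix(["A", "B"], ["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        upgma(m)
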