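"""Nei FST estimator (against an independently coded textbook oracle),
permutation significance, PCA and the balanced-subsampling contrast."""

import numpy as np
import pytest

from sievekit import (
    balanced_subsample_contrast,
    fst_permutation_test,
    nei_pairwise_fst,
    pca_genotypes,
)
from sievekit.datatypes import MISSING, GenotypeMatrix

from conftest import make_gm


# ----------------------------------------------------------------------
# textbook-formula oracle, coded independently with plain scalar loops
# ----------------------------------------------------------------------

def oracle_nei_fst(geno, labels):
    labels = list(labels)
    groups = sorted(set(labels))
    assert len(groups) == 2
    dst_sum = 0.0
    ht_sum = 0.0
    for j in range(geno.n_loci):
        ns, ps, hos = [], [], []
        for grp in groups:
            rows = [i for i, l in enumerate(labels) if l == grp]
            calls = [geno.genotypes[i, j] for i in rows if geno.genotypes[i, j] != MISSING]
            if len(calls) < 2:
                ns = []
                break
            ns.append(len(calls))
            ps.append(sum(calls) / (2 * len(calls)))
            hos.append(sum(1 for g in calls if g == 1) / len(calls))
        if not ns:
            continue
        k = 2
        p_bar = sum(ps) / k
        if p_bar in (0.0, 1.0):
            continue
        n_harm = k / sum(1.0 / n for n in ns)
        ho = sum(hos) / k
        hs_raw = sum(2 * p * (1 - p) for p in ps) / k
        hs = n_harm / (n_harm - 1) * (hs_raw - ho / (2 * n_harm))
        ht = 2 * p_bar * (1 - p_bar) + hs / (n_harm * k) - ho / (2 * n_harm * k)
        dst_sum += ht - hs
        ht_sum += ht
    return dst_sum / ht_sum


def test_fixed_differences_give_fst_of_one():
    gm = make_gm([[0, 0, 0], [0, 0, 0], [2, 2, 2], [2, 2, 2]])
    res = nei_pairwise_fst(gm, ["A", "A", "B", "B"])
    assert res.fst.loc["A", "B"] == pytest.approx(1.0)


def test_hand_fixture_matches_textbook_oracle_to_machine_precision():
    rng = np.random.default_rng(2)
    g = rng.choice([0, 1, 2, MISSING], size=(14, 6), p=[0.4, 0.3, 0.2, 0.1])
    gm = make_gm(g.astype(np.int8))
    labels = ["A"] * 7 + ["B"] * 7
    res = nei_pairwise_fst(gm, labels)
    assert res.fst.loc["A", "B"] == pytest.approx(
        oracle_nei_fst(gm, labels), abs=1e-12
    )


def test_identical_source_populations_estimate_near_zero():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.9, size=4000)
    g = rng.binomial(2, p, size=(600, 4000)).astype(np.int8)
    gm = make_gm(g)
    labels = ["A"] * 300 + ["B"] * 300
    res = nei_pairwise_fst(gm, labels)
    assert abs(res.fst.loc["A", "B"]) < 0.005


def test_group_against_its_own_copy_is_zero_to_tolerance():
    rng = np.random.default_rng(4)
    g = rng.choice([0, 1, 2], size=(20, 50), p=[0.5, 0.3, 0.2]).astype(np.int8)
    dup = np.vstack([g, g])
    gm = make_gm(dup)
    labels = ["A"] * 20 + ["B"] * 20
    res = nei_pairwise_fst(gm, labels)
    assert res.fst.loc["A", "B"] == pytest.approx(
        oracle_nei_fst(gm, labels), abs=1e-12
    )


def test_balding_nichols_recovery_of_target_divergence():
    """Mean estimated pairwise FST over replicate simulations within 20%
    of the configured divergence at 0.01 and 0.03."""
    from sievekit import SieveConfig, simulate_ancestral_populations

    rng = np.random.default_rng(8)
    for target in (0.01, 0.03):
        ests = []
        for rep in range(30):
            cfg = SieveConfig(
                n_populations=2, n_loci=2000, target_fst=target,
                sieve_loci={2014: {}, 2015: {}}, gradient_loci={},
                missing_rate=0.0, n_replicate_pairs=0, seed=900 + rep,
            )
            freqs = simulate_ancestral_populations(cfg)
            g = np.vstack(
                [rng.binomial(2, freqs.freqs[i], size=(50, 2000)) for i in (0, 1)]
            ).astype(np.int8)
            gm = make_gm(g)
            res = nei_pairwise_fst(gm, ["A"] * 50 + ["B"] * 50)
            ests.append(res.fst.loc["A", "B"])
        assert abs(np.mean(ests) - target) < 0.2 * target


def test_perfect_differentiation_has_minimal_permutation_p():
    # groups of 20 so no permutation re-creates the split by chance
    gm = make_gm(
        np.vstack([np.zeros((20, 20)), np.full((20, 20), 2)]).astype(np.int8)
    )
    labels = ["A"] * 20 + ["B"] * 20
    res = fst_permutation_test(gm, labels, B=999, seed=0)
    assert res.p_values.loc["A", "B"] == pytest.approx(0.001)


def test_permutation_p_deterministic_under_seed():
    rng = np.random.default_rng(6)
    g = rng.choice([0, 1, 2], size=(30, 40)).astype(np.int8)
    gm = make_gm(g)
    labels = ["A"] * 15 + ["B"] * 15
    a = fst_permutation_test(gm, labels, B=199, seed=3)
    b = fst_permutation_test(gm, labels, B=199, seed=3)
    assert a.p_values.equals(b.p_values)


def test_null_permutation_p_is_uniform():
    """Labels drawn from one population give uniform permutation p."""
    from scipy import stats

    rng = np.random.default_rng(7)
    ps = []
    for rep in range(200):
        p = rng.uniform(0.2, 0.8, size=300)
        g = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
        gm = make_gm(g)
        labels = ["A"] * 20 + ["B"] * 20
        res = fst_permutation_test(gm, labels, B=99, seed=rep)
        ps.append(res.p_values.loc["A", "B"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def test_duplicated_individual_gets_identical_scores():
    rng = np.random.default_rng(10)
    g = rng.choice([0, 1, 2], size=(10, 30)).astype(np.int8)
    g[5] = g[4]
    res = pca_genotypes(make_gm(g))
    assert np.allclose(res.scores[4], res.scores[5])


def test_two_fixed_clusters_are_split_by_pc1_with_zero_within_variance():
    g = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)]).astype(np.int8)
    res = pca_genotypes(make_gm(g))
    pc1 = res.scores[:, 0]
    assert res.scores[:5, 0].std() < 1e-10
    assert res.scores[5:, 0].std() < 1e-10
    assert abs(pc1[:5].mean() - pc1[5:].mean()) > 1.0


def test_eigenvalues_match_independent_eigendecomposition():
    rng = np.random.default_rng(12)
    g = rng.choice([0, 1, 2], size=(6, 4)).astype(np.int8)
    gm = make_gm(g)
    res = pca_genotypes(gm)
    x = g.astype(float)
    x = x[:, x.std(axis=0) > 0]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    cov = x.T @ x / (x.shape[0] - 1)
    expect = np.sort(np.linalg.eigvalsh(cov))[::-1]
    assert np.allclose(res.eigenvalues, expect[: len(res.eigenvalues)], atol=1e-10)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_zero_variance_loci_are_dropped_and_reported():
    g = np.array(
        [[0, 1, 1, 2], [0, 2, 1, 0], [0, 0, 1, 1], [0, 1, 1, 2]], dtype=np.int8
    )
    res = pca_genotypes(make_gm(g))
    assert set(res.dropped_loci) == {"L0", "L2"}
    assert set(res.kept_loci) == {"L1", "L3"}


def test_pca_requires_complete_matrix():
    with pytest.raises(ValueError, match="impute"):
        pca_genotypes(make_gm([[0, MISSING], [1, 2], [0, 1]]))


# ----------------------------------------------------------------------
# balanced subsampling
# ----------------------------------------------------------------------

def _structured_matrix(sizes, rng, l=300, spread=4.0):
    blocks, labels = [], []
    anc = rng.uniform(0.2, 0.8, size=l)
    for grp, n in sizes.items():
        p = np.clip(anc + rng.normal(0, 0.05 * spread, size=l), 0.02, 0.98)
        blocks.append(rng.binomial(2, p, size=(n, l)))
        labels += [grp] * n
    return make_gm(np.vstack(blocks).astype(np.int8)), labels


def test_balanced_subsampling_fst_stable_while_pca_moves():
    rng = np.random.default_rng(13)
    gm, labels = _structured_matrix({"A": 60, "B": 45, "C": 30, "D": 15}, rng)
    summary = balanced_subsample_contrast(gm, labels, n_eq=15, R=20, seed=1)
    assert (summary.fst_cv() < 0.5).all()
    assert summary.fst_draws.shape == (20, 6)
    assert summary.pc_shares["PC1"].std() > 0


def test_balanced_subsampling_boundary_and_errors():
    rng = np.random.default_rng(14)
    gm, labels = _structured_matrix({"A": 12, "B": 10}, rng, l=60)
    summary = balanced_subsample_contrast(gm, labels, n_eq=10, R=5, seed=2)
    again = balanced_subsample_contrast(gm, labels, n_eq=10, R=5, seed=2)
    assert summary.fst_draws.equals(again.fst_draws)
    with pytest.raises(ValueError, match="smallest group"):
        balanced_subsample_contrast(gm, labels, n_eq=11, R=5, seed=2)
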