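"""Statistical-battery tests against hand oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from qeegrecovery.stats import (compare_groups, km_logrank, roc_auc_ci,
                                spearman_ci)

# ------------------------------------------------------------ group compare


def test_identical_groups_show_no_difference():
    x = np.random.default_rng(0).normal(0, 1, 20)
    res = compare_groups(x, x)
    assert res.p_value >= 0.99


def test_skewed_group_forces_rank_sum():
    rng = np.random.default_rng(1)
    a = rng.normal(10, 1, 30)
    b = np.exp(rng.normal(0, 1.5, 30)) + 8  # heavily right-skewed
    res = compare_groups(a, b)
    assert res.test_used == "rank-sum"
    assert not res.normal_b


def test_small_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_power_on_study_sized_twa_groups():
    """Normal(0.66, 0.09^2) vs Normal(0.52, 0.17^2), n = 20 each: the gated
    comparison rejects at alpha = 0.05 in at least 80% of 500 replicates
    (Monte-Carlo power computation)."""
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 500
    for _ in range(n_rep):
        a = rng.normal(0.66, 0.09, 20)
        b = rng.normal(0.52, 0.17, 20)
        if compare_groups(a, b).p_value < 0.05:
            hits += 1
    assert hits / n_rep >= 0.8


# ----------------------------------------------------------------- Spearman

def test_spearman_rank_formula_oracle():
    """x=[1..5], y=[2,1,4,3,5]: 1 - 6*4/(5*24) = 0.8 exactly."""
    res = spearman_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert abs(res.r - 0.8) < 1e-12
    assert res.ci_low <= res.r <= res.ci_high


def test_spearman_perfect_monotone():
    x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
    assert spearman_ci(x, np.exp(x)).r == pytest.approx(1.0, abs=1e-12)
    assert spearman_ci(x, -x).r == pytest.approx(-1.0, abs=1e-12)


def test_spearman_matches_brute_force_on_unique_values(rng):
    x = rng.permutation(30).astype(float)
    y = rng.permutation(30).astype(float)
    d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
    brute = 1 - 6 * np.sum(d**2) / (30 * (30**2 - 1))
    assert abs(spearman_ci(x, y).r - brute) < 1e-12


def test_spearman_fisher_ci_brackets_r_and_shrinks_with_n(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(scale=0.8, size=50)
    res = spearman_ci(x, y)
    assert res.ci_low < res.r < res.ci_high
    small = spearman_ci(x[:10], y[:10])
    assert (res.ci_high - res.ci_low) < (small.ci_high - small.ci_low)


def test_spearman_constant_input_is_error():
    with pytest.raises(ValueError):
        spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------- AUC

def test_auc_tie_handling_oracle():
    """Survivors [1,2,3] vs non-survivors [2,3,4]: 9 pairs, 6 concordant +
    2 ties -> AUC = 7/9 exactly."""
    scores = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
    survived = np.array([True, True, True, False, False, False])
    res = roc_auc_ci(scores, survived, n_bootstrap=100)
    assert abs(res.auc - 7.0 / 9.0) < 1e-12


def test_auc_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    survived = np.array([True] * 3 + [False] * 3)
    assert roc_auc_ci(scores, survived, n_bootstrap=100).auc == 1.0


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.uniform(1.0, 9.0, size=40)
    survived = rng.uniform(size=40) > 0.4
    if survived.all() or not survived.any():
        survived[:5] = ~survived[:5]
    a = roc_auc_ci(scores, survived, n_bootstrap=50).auc
    b = roc_auc_ci(np.log(scores), survived, n_bootstrap=50).auc
    c = roc_auc_ci(scores**3, survived, n_bootstrap=50).auc
    assert a == b == c


def test_auc_null_near_half(rng):
    scores = rng.normal(size=400)
    survived = rng.uniform(size=400) > 0.5
    res = roc_auc_ci(scores, survived, n_bootstrap=100)
    assert abs(res.auc - 0.5) < 0.08
    assert res.ci_low <= res.auc <= res.ci_high


def test_auc_single_class_is_error():
    with pytest.raises(ValueError):
        roc_auc_ci([1.0, 2.0], [True, True])


def test_auc_risk_direction_orients_twa_features():
    # low TWA = high risk: perfect discrimination when negated
    scores = np.array([0.7, 0.8, 0.6, 0.2, 0.3, 0.1])
    survived = np.array([True] * 3 + [False] * 3)
    res = roc_auc_ci(scores, survived, risk_direction="lower_worse",
                     n_bootstrap=50)
    assert res.auc == 1.0


# --------------------------------------------------------------- KM/logrank

def test_km_product_limit_hand_oracle():
    """Four deaths at 1,2,3,4: S steps 0.75, 0.5, 0.25, 0; median = 2."""
    res = km_logrank([1, 2, 3, 4], [1, 1, 1, 1], ["a"] * 4)
    sf = res.survival_functions["a"]
    steps = sf[sf.time_h > 0].S.to_numpy()
    np.testing.assert_allclose(steps, [0.75, 0.5, 0.25, 0.0])
    assert res.medians["a"] == 2.0


def test_km_no_deaths_means_flat_curve_and_undefined_median():
    res = km_logrank([96.0] * 6, [0] * 6, ["a"] * 6)
    assert (res.survival_functions["a"].S == 1.0).all()
    assert np.isinf(res.medians["a"])


def test_km_without_censoring_is_empirical_survival():
    rng = np.random.default_rng(5)
    t = rng.uniform(1.0, 90.0, size=25)
    res = km_logrank(t, np.ones(25), ["a"] * 25)
    sf = res.survival_functions["a"]
    for time, s in zip(sf.time_h, sf.S):
        assert abs(s - np.mean(t > time)) < 1e-12


def test_logrank_zero_for_identical_groups():
    t = [10.0, 20.0, 30.0, 96.0, 96.0] * 2
    e = [1, 1, 1, 0, 0] * 2
    g = ["a"] * 5 + ["b"] * 5
    res = km_logrank(t, e, g)
    assert res.logrank_statistic < 1e-9
    assert res.logrank_p > 0.99


def test_logrank_p_uniform_under_permutation(rng):
    """With group labels permuted at random the log-rank p-value is uniform
    on [0, 1] (coarse KS check at 200 permutations)."""
    t = rng.uniform(1.0, 96.0, size=40)
    e = rng.uniform(size=40) > 0.3
    pvals = []
    for _ in range(200):
        g = rng.permutation(["a"] * 20 + ["b"] * 20)
        pvals.append(km_logrank(t, e, g).logrank_p)
    d, p = sps.kstest(pvals, "uniform")
    assert p > 0.001


def test_km_input_validation():
    with pytest.raises(ValueError):
        km_logrank([0.0, 1.0], [1, 1], ["a", "a"])
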