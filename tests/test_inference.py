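"""Permutation ANOVA/contrasts, classical fits and diagnostics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from semrec import (
    ancova,
    normality,
    one_way_anova,
    ols_regression,
    perm_anova,
    perm_anova_arrays,
    perm_contrast_arrays,
    variance_homogeneity,
)
from semrec.errors import (
    DegenerateVarianceError,
    DesignError,
    SemrecError,
    SingularDesignError,
)
from semrec.inference import _build_design, _sequential_ss


# ---------------------------------------------------------------------------
# permutation ANOVA


def test_single_factor_exhaustive_matches_enumeration():
    """{1,2,3} vs {10,11,12}: only the 2 extreme of the C(6,3)=20 splits
    reach the observed F, so the exact p is 0.1."""
    y = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    labels = ["a"] * 3 + ["b"] * 3
    tab = perm_anova_arrays(y, {"g": labels})
    term = tab["g"]
    assert term.exhaustive
    assert term.p == pytest.approx(2 / 20)


def test_constant_response_gives_p_one(study_table):
    n = 12
    y = [5.0] * n
    labels = ["a", "b"] * 6
    tab = perm_anova_arrays(y, {"g": labels}, max_iter=200, seed=0)
    assert tab["g"].p == 1.0


def test_iteration_and_p_contract_bounds(study_table):
    tab = perm_anova(study_table, seed=5, max_iter=5000, min_iter=50)
    for t in tab.terms:
        assert t.iterations <= 5000
        assert t.p >= 1.0 / (t.iterations + 1)
        assert 0.0 < t.p <= 1.0


def test_factorial_terms_and_dfs(study_table):
    tab = perm_anova(study_table, seed=5)
    names = [t.term for t in tab.terms]
    assert names == ["time", "temp", "food", "time:temp", "time:food",
                     "temp:food", "time:temp:food"]
    assert all(t.df == 1 for t in tab.terms)
    n_recovery = sum(
        1 for r in study_table.records
        if r.period_days > 0 and r.electroejaculated
    )
    assert tab.residual_df == n_recovery - 8


def test_stopping_rule_spends_iterations_where_p_is_small(study_table):
    """Clearly non-significant terms stop early; significant ones run to
    the cap — the qualitative iteration pattern of sequential stopping."""
    tab = perm_anova(study_table, seed=5)
    small_p = [t for t in tab.terms if t.p < 0.01]
    big_p = [t for t in tab.terms if t.p > 0.4]
    assert all(t.iterations == 5000 for t in small_p)
    assert all(t.iterations < 1000 for t in big_p)


def test_sequential_ss_matches_statsmodels_type1():
    """Oracle: Type I SS on an unbalanced two-factor design must equal
    statsmodels anova_lm(typ=1)."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(1)
    f1 = np.array(["a"] * 5 + ["b"] * 8)
    f2 = np.array(["x", "y"] * 6 + ["x"])
    y = rng.normal(size=13) + (f1 == "b") * 0.5
    X, terms, sizes = _build_design({"f1": f1, "f2": f2})
    Q, _ = np.linalg.qr(X)
    ss = _sequential_ss(Q, sizes, y[:, None])[:, 0]
    df = pd.DataFrame({"y": y, "f1": f1, "f2": f2})
    fit = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    assert ss[1] == pytest.approx(tab.loc["C(f1)", "sum_sq"])
    assert ss[2] == pytest.approx(tab.loc["C(f2)", "sum_sq"])
    assert ss[3] == pytest.approx(tab.loc["C(f1):C(f2)", "sum_sq"])


def test_balanced_design_order_invariant_ss():
    rng = np.random.default_rng(2)
    f1 = np.repeat(["a", "b"], 8)
    f2 = np.tile(np.repeat(["x", "y"], 4), 2)
    y = rng.normal(size=16)
    Xa, _, sa = _build_design({"f1": f1, "f2": f2})
    Xb, _, sb = _build_design({"f2": f2, "f1": f1})
    ssa = _sequential_ss(np.linalg.qr(Xa)[0], sa, y[:, None])[:, 0]
    ssb = _sequential_ss(np.linalg.qr(Xb)[0], sb, y[:, None])[:, 0]
    # main effects swap position but keep their SS on a balanced design
    assert ssa[1] == pytest.approx(ssb[2])
    assert ssa[2] == pytest.approx(ssb[1])


def test_permutation_p_invariant_under_monotone_relabeling():
    rng = np.random.default_rng(3)
    y = rng.normal(size=14).tolist()
    labels = (["a"] * 7 + ["b"] * 7)
    relabeled = ["group2" if l == "b" else "group1" for l in labels]
    p1 = perm_anova_arrays(y, {"g": labels}, seed=11)["g"].p
    p2 = perm_anova_arrays(y, {"g": relabeled}, seed=11)["g"].p
    assert p1 == p2


def test_empty_factor_level_and_saturated_model_error():
    with pytest.raises(DesignError):
        perm_anova_arrays([1.0, 2.0, 3.0], {"g": ["a", "a", "a"]})
    with pytest.raises(DesignError):
        perm_anova_arrays([1.0, 2.0], {"g": ["a", "b"]})


# ---------------------------------------------------------------------------
# permutation contrasts


def brute_force_contrast_p(x1, x2):
    """Independent oracle: enumerate every label split."""
    pooled = list(x1) + list(x2)
    n1 = len(x1)
    obs = abs(np.mean(x1) - np.mean(x2))
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(np.mean(g1) - np.mean(g2)) >= obs - 1e-12:
            count += 1
    return count / total


def test_contrast_of_identical_groups_is_null():
    res = perm_contrast_arrays([6.0, 6.1, 5.9], [6.0, 6.1, 5.9])
    assert res.estimate == pytest.approx(0.0)
    assert res.p == 1.0


def test_constant_groups_contrast_exact():
    """{6,6,6,6} vs {8.5 x 4}: only the two extreme of the C(8,4)=70 splits
    attain |difference| >= 2.5."""
    res = perm_contrast_arrays([6.0] * 4, [8.5] * 4)
    assert res.exhaustive
    assert res.estimate == pytest.approx(-2.5)
    assert res.p == pytest.approx(2 / 70)


@pytest.mark.parametrize("seed", range(6))
def test_exhaustive_contrast_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, 3).round(2).tolist()
    x2 = rng.normal(0.8, 1, 3).round(2).tolist()
    res = perm_contrast_arrays(x1, x2)
    assert res.exhaustive
    assert res.p == pytest.approx(brute_force_contrast_p(x1, x2))
    assert res.p >= 2 / 20  # two-sided minimum for 3 vs 3 distinct values


def test_contrast_sign_convention():
    # a comparison group above baseline yields a negative estimate
    res = perm_contrast_arrays([6.0, 6.2], [8.4, 8.6])
    assert res.estimate < 0


def test_degenerate_single_member_contrast():
    with pytest.raises(SemrecError):
        perm_contrast_arrays([5.0], [5.0])


def test_monte_carlo_contrast_respects_cap_and_floor():
    rng = np.random.default_rng(4)
    x1 = rng.normal(0, 1, 12).tolist()
    x2 = rng.normal(2.5, 1, 12).tolist()  # C(24,12) >> exhaustive limit
    res = perm_contrast_arrays(x1, x2, max_iter=800, seed=0)
    assert not res.exhaustive
    assert res.iterations <= 800
    assert res.p >= 1.0 / (res.iterations + 1)


# ---------------------------------------------------------------------------
# classical fits


def test_one_way_anova_hand_computed():
    # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4 -> F = 1.5, df (1, 4)
    res = one_way_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
    t = res.term("groups")
    assert t.F == pytest.approx(1.5)
    assert (t.df_num, t.df_den) == (1, 4)
    assert t.p == pytest.approx(float(stats.f.sf(1.5, 1, 4)))


def test_one_way_anova_identical_groups():
    res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res.term("groups").F == 0.0
    assert res.term("groups").p == 1.0


def test_one_way_anova_degenerate_cases():
    with pytest.raises(DesignError):
        one_way_anova([1, 2, 3], ["a", "a", "a"])
    res = one_way_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
    assert res.infinite_f and math.isinf(res.term("groups").F)


def test_regression_perfect_fit_flagged():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2 * v + 1 for v in x]
    res = ols_regression(y, x)
    assert res.coefficients["slope"] == pytest.approx(2.0)
    assert res.coefficients["intercept"] == pytest.approx(1.0)
    assert res.adjusted_r2 == 1.0
    assert res.infinite_f


def test_adjusted_r2_negative_iff_f_below_one():
    """For simple regression, adjusted R2 < 0 exactly when F < 1 — the
    convention that lets a printed headline R2 be negative."""
    rng = np.random.default_rng(0)
    seen_negative = False
    for _ in range(20):
        y = rng.normal(size=28)
        x = rng.normal(size=28)
        res = ols_regression(y, x)
        f = res.term("slope").F
        assert (res.adjusted_r2 < 0) == (f < 1.0)
        seen_negative |= res.adjusted_r2 < 0
    assert seen_negative


def test_regression_preconditions():
    with pytest.raises(DesignError):
        ols_regression([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(SingularDesignError):
        ols_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_ancova_matches_hand_built_sequential_fit():
    """Oracle: on a balanced design with the covariate orthogonal to the
    factor, recompute both sequential F statistics from a hand-built
    (QR-projection) fit; the factor SS equals the one-way between-group SS,
    so the factor F differs from the one-way F only via the residual."""
    rng = np.random.default_rng(5)
    factor = np.array(["a"] * 6 + ["b"] * 6)
    cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)  # same per group
    y = rng.normal(size=12) + (factor == "b") * 1.5
    res = ancova(y, factor, cov)

    # hand-built sequential fit: intercept | factor dummy | covariate
    X = np.column_stack([np.ones(12), (factor == "b").astype(float), cov])
    Q, _ = np.linalg.qr(X)
    ss = _sequential_ss(Q, [1, 1, 1], y[:, None])[:, 0]
    ss_res = float(y @ y) - ss.sum()
    f_factor = ss[1] / (ss_res / 9)
    f_cov = ss[2] / (ss_res / 9)
    assert res.term("factor").F == pytest.approx(f_factor)
    assert res.term("covariate").F == pytest.approx(f_cov)
    assert res.term("factor").df_den == 9

    # orthogonality: the factor's sequential SS is the one-way SSB
    ssw = sum(
        float(np.sum((y[factor == g] - y[factor == g].mean()) ** 2))
        for g in np.unique(factor)
    )
    ow_f = one_way_anova(y, factor).term("groups")
    ssb = ow_f.F * ssw / ow_f.df_den
    assert ss[1] == pytest.approx(ssb)


def test_ancova_null_factor_p_uniform():
    """y driven only by the covariate, covariate orthogonal to the factor:
    the factor p-value is uniform. (Orthogonality matters: the factor is
    fitted first in the sequential order, so a covariate correlated with
    the factor by chance would leak signal into the factor term.)"""
    rng = np.random.default_rng(6)
    cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)  # same per group
    ps = []
    for _ in range(500):
        y = 2.0 * cov + rng.normal(size=12)
        ps.append(ancova(y, ["a"] * 6 + ["b"] * 6, cov).term("factor").p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_ancova_design_errors():
    with pytest.raises(DesignError):
        ancova([1.0, 2.0, 3.0], ["a", "a", "a"], [1.0, 2.0, 3.0])
    with pytest.raises(SingularDesignError):
        ancova([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], [5.0, 5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# diagnostics


def test_bartlett_equal_variances_is_zero():
    k2, p = variance_homogeneity([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert k2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_bartlett_detects_gross_heteroscedasticity():
    rng = np.random.default_rng(7)
    vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 10, 10)])
    k2, p = variance_homogeneity(vals, ["a"] * 10 + ["b"] * 10)
    assert p < 0.001


def test_bartlett_matches_scipy():
    rng = np.random.default_rng(8)
    a, b, c = rng.normal(0, 1, 7), rng.normal(0, 2, 9), rng.normal(0, 1.5, 5)
    vals = np.concatenate([a, b, c])
    labels = ["a"] * 7 + ["b"] * 9 + ["c"] * 5
    k2, p = variance_homogeneity(vals, labels)
    ref = stats.bartlett(a, b, c)
    assert k2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_bartlett_degenerate_cases():
    with pytest.raises(DesignError):
        variance_homogeneity([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(DegenerateVarianceError):
        variance_homogeneity([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])


def test_normality_contract():
    rng = np.random.default_rng(9)
    w, p = normality(rng.normal(size=30))
    assert 0 < w <= 1
    assert 0 <= p <= 1
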