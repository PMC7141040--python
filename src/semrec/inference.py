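"""Permutation inference for the hepatosomatic index, plus classical fits.

The factorial analysis is a permutation ANOVA: a full-factorial linear model
(main effects in the order time, temperature, food, then the two-way and the
three-way interactions) with sequential (Type I) sums of squares on the
possibly unbalanced design. Each term's p-value comes from unrestricted
permutation of the raw response across all records, refitting per
permutation, with the valid estimator p = (b + 1) / (m + 1) where b counts
permuted F statistics at least as large as the observed one. A per-term
sequential stopping rule ends sampling once the p estimate is stable
(estimated SE below 0.1 * p after a minimum number of iterations), so
clearly non-significant terms use few iterations while significant ones run
to the cap. When the number of distinct response arrangements is small
(<= 20,000) the permutation distribution is enumerated exhaustively and the
p-value is exact (b / m, the identity arrangement included).

Pairwise contrasts permute cell labels between two groups with statistic
|mean difference|; the reported estimate is baseline mean minus comparison
mean, so a group whose index rose above baseline has a negative estimate.

The classical fits (one-way ANOVA, OLS regression reporting adjusted R2 as
the headline statistic, one-way ANCOVA with sequential SS) and the
diagnostics (Bartlett's variance-homogeneity test by its closed form,
Shapiro-Wilk normality) round out the module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Cell, StudyTable, record_value
from .errors import (
    DegenerateVarianceError,
    DesignError,
    SemrecError,
    SingularDesignError,
)

#: Exhaustive enumeration is used when the number of distinct response
#: arrangements does not exceed this.
EXHAUSTIVE_LIMIT = 20_000

#: Relative tolerance when comparing permuted statistics with the observed
#: one (float noise must not break exact ties).
_TIE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# results


@dataclass
class PermTermResult:
    term: str
    df: int
    ms: float
    iterations: int
    p: float
    exhaustive: bool = False


@dataclass
class PermAnovaTable:
    """Factorial permutation-ANOVA table (one row per term + residuals)."""

    terms: list[PermTermResult]
    residual_df: int
    residual_ms: float
    seed: Optional[int] = None

    def __getitem__(self, term: str) -> PermTermResult:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"term": t.term, "df": t.df, "ms": t.ms,
             "iterations": t.iterations, "p": t.p}
            for t in self.terms
        ]
        rows.append({"term": "residuals", "df": self.residual_df,
                     "ms": self.residual_ms, "iterations": None, "p": None})
        return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    baseline: str
    comparison: str
    estimate: float     # baseline mean - comparison mean
    iterations: int
    p: float
    exhaustive: bool = False


@dataclass
class TermStat:
    term: str
    df_num: int
    df_den: int
    F: float
    p: float


@dataclass
class LinearFitResult:
    """Classical linear-model fit: coefficients plus per-term F tests."""

    coefficients: dict[str, float]
    terms: list[TermStat]
    adjusted_r2: Optional[float] = None
    infinite_f: bool = False

    def term(self, name: str) -> TermStat:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# design matrices and sequential SS


def _dummy_columns(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Drop-first treatment coding: one column per non-reference level."""
    return np.column_stack([(values == lev).astype(float) for lev in levels[1:]])


def _build_design(
    factor_values: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, list[str], list[int]]:
    """Ordered full-factorial design matrix.

    Returns (X, term_names, block_sizes): X starts with the intercept
    column, then one block per term in entry order (mains, two-way
    interactions in the induced order, then the highest-order interaction).
    """
    names = list(factor_values)
    n = len(next(iter(factor_values.values())))
    main_cols: dict[str, np.ndarray] = {}
    for name in names:
        vals = np.asarray(factor_values[name])
        levels = np.unique(vals)
        if levels.size < 2:
            raise DesignError(f"factor {name!r} has fewer than 2 levels")
        main_cols[name] = _dummy_columns(levels, vals)

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    term_names: list[str] = []
    for order in range(1, len(names) + 1):
        for combo in itertools.combinations(names, order):
            cols = main_cols[combo[0]]
            for other in combo[1:]:
                cols = np.einsum("ni,nj->nij", cols, main_cols[other]).reshape(n, -1)
            blocks.append(cols)
            term_names.append(":".join(combo))
    X = np.hstack(blocks)
    sizes = [b.shape[1] for b in blocks]
    return X, term_names, sizes


def _sequential_ss(Q: np.ndarray, sizes: Sequence[int], Y: np.ndarray) -> np.ndarray:
    """Type I sums of squares per block for each response column of Y.

    Q is the orthonormal factor of the ordered design matrix; the SS
    attributed to a block is the squared norm of its rows of Q^T Y, which
    is exactly the sequential increment in explained SS.
    """
    C = Q.T @ Y  # (p, m)
    out = np.empty((len(sizes), Y.shape[1]))
    start = 0
    for bi, size in enumerate(sizes):
        out[bi] = np.sum(C[start:start + size] ** 2, axis=0)
        start += size
    return out


def _f_from_ss(ss_terms, df_terms, ss_res, df_res):
    """Per-term F, mapping 0/0 to 0 and x/0 (x>0) to inf."""
    ms_res = ss_res / df_res if df_res > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_terms / df_terms[:, None]) / ms_res
    F = np.where(np.isnan(F), 0.0, F)
    return F


def _multiset_permutations(values: Sequence):
    """Distinct permutations of a multiset, lexicographic."""

    def rec(counter: dict, length: int):
        if length == 0:
            yield ()
            return
        for v in counter:
            if counter[v] > 0:
                counter[v] -= 1
                for rest in rec(counter, length - 1):
                    yield (v,) + rest
                counter[v] += 1

    counts: dict = {}
    for v in sorted(values):
        counts[v] = counts.get(v, 0) + 1
    return rec(counts, len(values))


def _n_distinct_permutations(values: Sequence) -> int:
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    total = math.factorial(len(values))
    for c in counts.values():
        total //= math.factorial(c)
    return total


# ---------------------------------------------------------------------------
# permutation ANOVA


def _stop_scan(b, m, exceed_chunk, min_iter):
    """First index in the chunk where the stopping rule fires, or None.

    Rule: after min_iter total iterations, stop once the binomial SE of
    p_hat = (b+1)/(m+1) falls below 0.1 * p_hat.
    """
    bc = b + np.cumsum(exceed_chunk)
    mc = m + np.arange(1, len(exceed_chunk) + 1)
    p = (bc + 1) / (mc + 1)
    se = np.sqrt(p * (1 - p) / mc)
    ok = (mc >= min_iter) & (se < 0.1 * p)
    idx = np.nonzero(ok)[0]
    return (int(idx[0]), int(bc[idx[0]]), int(mc[idx[0]])) if idx.size else None


def perm_anova_arrays(
    y: Sequence[float],
    factors: Mapping[str, Sequence],
    max_iter: int = 5000,
    min_iter: int = 50,
    seed: Optional[int] = None,
    chunk: int = 256,
) -> PermAnovaTable:
    """Permutation ANOVA on raw arrays (see module docstring for the model)."""
    y = np.asarray(y, dtype=float)
    factor_values = {k: np.asarray(v) for k, v in factors.items()}
    for name, vals in factor_values.items():
        if len(vals) != y.size:
            raise DesignError(f"factor {name!r} length mismatch")

    X, term_names, sizes = _build_design(factor_values)
    n, p_cols = X.shape
    df_res = n - p_cols
    if df_res <= 0:
        raise DesignError("saturated model: zero residual degrees of freedom")
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise SingularDesignError("rank-deficient factorial design")

    df_terms = np.array(sizes[1:], dtype=int)  # skip intercept block
    yy = float(y @ y)

    def stats_for(Y: np.ndarray) -> np.ndarray:
        ss = _sequential_ss(Q, sizes, Y)
        ss_res = np.maximum(np.sum(Y**2, axis=0) - ss.sum(axis=0), 0.0)
        return _f_from_ss(ss[1:], df_terms, ss_res, df_res), ss, ss_res

    F_obs_mat, ss_obs, ss_res_obs = stats_for(y[:, None])
    F_obs = F_obs_mat[:, 0]
    thresh = F_obs * (1 - _TIE_RTOL)
    ms_obs = ss_obs[1:, 0] / df_terms
    ms_res = float(ss_res_obs[0] / df_res)

    nt = len(term_names)

    if _n_distinct_permutations(list(y)) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(_multiset_permutations(list(y))), dtype=float).T
        F_perm, _, _ = stats_for(perms)
        m = perms.shape[1]
        b = (F_perm >= thresh[:, None]).sum(axis=1)
        terms = [
            PermTermResult(term_names[t], int(df_terms[t]), float(ms_obs[t]),
                           int(m), float(b[t] / m), exhaustive=True)
            for t in range(nt)
        ]
        return PermAnovaTable(terms, df_res, ms_res, seed=seed)

    rng = np.random.default_rng(seed)
    b_cnt = np.zeros(nt, dtype=int)
    m_cnt = np.zeros(nt, dtype=int)
    done = np.zeros(nt, dtype=bool)
    result_bm = [None] * nt
    total = 0
    while total < max_iter and not done.all():
        L = min(chunk, max_iter - total)
        Yp = rng.permuted(np.broadcast_to(y, (L, y.size)), axis=1).T.copy()
        F_perm, _, _ = stats_for(Yp)
        exceed = F_perm >= thresh[:, None]
        for t in range(nt):
            if done[t]:
                continue
            hit = _stop_scan(b_cnt[t], m_cnt[t], exceed[t], min_iter)
            if hit is not None:
                _, bt, mt = hit
                result_bm[t] = (bt, mt)
                done[t] = True
            else:
                b_cnt[t] += int(exceed[t].sum())
                m_cnt[t] += L
        total += L
    for t in range(nt):
        if result_bm[t] is None:
            result_bm[t] = (int(b_cnt[t]), int(m_cnt[t]))

    terms = []
    for t in range(nt):
        bt, mt = result_bm[t]
        terms.append(
            PermTermResult(term_names[t], int(df_terms[t]), float(ms_obs[t]),
                           mt, (bt + 1) / (mt + 1))
        )
    return PermAnovaTable(terms, df_res, ms_res, seed=seed)


def perm_anova(
    table: StudyTable,
    response: str = "hsi",
    max_iter: int = 5000,
    min_iter: int = 50,
    seed: Optional[int] = None,
) -> PermAnovaTable:
    """Factorial permutation ANOVA of a response over time/temp/food.

    Uses the electroejaculated recovery records (period > 0); every one of
    the three factors must have at least two levels present.
    """
    recs = [r for r in table.records if r.period_days > 0 and r.electroejaculated]
    if not recs:
        raise DesignError("no recovery records (period > 0, electroejaculated)")
    if any(r.temperature is None for r in recs):
        raise DesignError("recovery records must carry a temperature")
    y = [record_value(r, response) for r in recs]
    factors = {
        "time": [r.period_days for r in recs],
        "temp": [r.temperature for r in recs],
        "food": [r.food for r in recs],
    }
    return perm_anova_arrays(
        y, factors, max_iter=max_iter, min_iter=min_iter, seed=seed
    )


# ---------------------------------------------------------------------------
# permutation contrast


def perm_contrast_arrays(
    baseline: Sequence[float],
    comparison: Sequence[float],
    max_iter: int = 5000,
    min_iter: int = 50,
    seed: Optional[int] = None,
    labels: tuple[str, str] = ("baseline", "comparison"),
) -> ContrastResult:
    """Two-group permutation test with statistic |mean difference|."""
    x1 = np.asarray(baseline, dtype=float)
    x2 = np.asarray(comparison, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise DesignError("both groups must be nonempty")
    if x1.size == 1 and x2.size == 1 and x1[0] == x2[0]:
        raise SemrecError("identical single-member groups: contrast degenerate")

    estimate = float(x1.mean() - x2.mean())
    observed = abs(estimate)
    thresh = observed * (1 - _TIE_RTOL)
    pooled = np.concatenate([x1, x2])
    n1, n = x1.size, x1.size + x2.size
    total_sum = float(pooled.sum())

    def absdiff_from_group1_sum(s1: np.ndarray) -> np.ndarray:
        return np.abs(s1 / n1 - (total_sum - s1) / (n - n1))

    n_splits = math.comb(n, n1)
    if n_splits <= EXHAUSTIVE_LIMIT:
        sums = np.fromiter(
            (pooled[list(c)].sum() for c in itertools.combinations(range(n), n1)),
            dtype=float,
            count=n_splits,
        )
        d = absdiff_from_group1_sum(sums)
        b = int((d >= thresh).sum())
        return ContrastResult(labels[0], labels[1], estimate, n_splits,
                              b / n_splits, exhaustive=True)

    rng = np.random.default_rng(seed)
    b_cnt = m_cnt = 0
    chunk = 512
    while m_cnt < max_iter:
        L = min(chunk, max_iter - m_cnt)
        perm = rng.permuted(np.broadcast_to(pooled, (L, n)), axis=1)
        d = absdiff_from_group1_sum(perm[:, :n1].sum(axis=1))
        hit = _stop_scan(b_cnt, m_cnt, d >= thresh, min_iter)
        if hit is not None:
            _, b_cnt, m_cnt = hit
            break
        b_cnt += int((d >= thresh).sum())
        m_cnt += L
    return ContrastResult(labels[0], labels[1], estimate, m_cnt,
                          (b_cnt + 1) / (m_cnt + 1))


def perm_contrast(
    table: StudyTable,
    baseline_cell: Cell,
    comparison_cell: Cell,
    response: str = "hsi",
    max_iter: int = 5000,
    min_iter: int = 50,
    seed: Optional[int] = None,
) -> ContrastResult:
    """Permutation contrast of a response between two design cells.

    The estimate is baseline mean minus comparison mean (a comparison group
    whose response rose above baseline yields a negative estimate).
    """
    base = [record_value(r, response) for r in table.cell_records(baseline_cell)]
    comp = [record_value(r, response) for r in table.cell_records(comparison_cell)]
    return perm_contrast_arrays(
        base, comp, max_iter=max_iter, min_iter=min_iter, seed=seed,
        labels=(baseline_cell.label(), comparison_cell.label()),
    )


# ---------------------------------------------------------------------------
# classical fits


def one_way_anova(values: Sequence[float], labels: Sequence) -> LinearFitResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [y[lab == g] for g in np.unique(lab)]
    k = len(groups)
    n = y.size
    if k < 2:
        raise DesignError("one-way ANOVA needs at least 2 groups")
    if n <= k:
        raise DesignError("no residual degrees of freedom")
    grand = y.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            F, p, flagged = 0.0, 1.0, False
        else:
            F, p, flagged = math.inf, 0.0, True
    else:
        F = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(F, df1, df2))
        flagged = False
    return LinearFitResult(
        coefficients={},
        terms=[TermStat("groups", df1, df2, float(F), p)],
        infinite_f=flagged,
    )


def ols_regression(y: Sequence[float], x: Sequence[float]) -> LinearFitResult:
    """Simple linear regression, reporting adjusted R2 as the headline R2.

    Adjusted R2 = 1 - (1 - R2)(n - 1)/(n - 2) can be negative when the
    regression explains less than one residual df worth of variance.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        raise DesignError("regression needs at least 3 observations")
    if np.ptp(x) == 0:
        raise SingularDesignError("constant regressor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    flagged = fit.ssr <= 1e-12 * max(tss, 1.0)
    if flagged:
        F, p, adj = math.inf, 0.0, 1.0
    else:
        F, p, adj = float(fit.fvalue), float(fit.f_pvalue), float(fit.rsquared_adj)
    return LinearFitResult(
        coefficients={"intercept": float(fit.params[0]), "slope": float(fit.params[1])},
        terms=[TermStat("slope", 1, int(y.size - 2), F, p)],
        adjusted_r2=adj,
        infinite_f=flagged,
    )


def ancova(
    y: Sequence[float], factor: Sequence, covariate: Sequence[float]
) -> LinearFitResult:
    """One-way ANCOVA: y ~ factor + covariate, sequential (Type I) SS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    fac = np.asarray(factor)
    levels = np.unique(fac)
    if levels.size < 2:
        raise DesignError("ANCOVA factor needs at least 2 levels")
    if np.ptp(cov) == 0:
        raise SingularDesignError("constant covariate")
    k = levels.size
    if y.size <= k + 1:
        raise DesignError("no residual degrees of freedom")
    df = pd.DataFrame({"y": y, "factor": fac.astype(str), "x": cov})
    fit = smf.ols("y ~ C(factor) + x", data=df).fit()
    if fit.df_resid != y.size - k - 1 or np.linalg.matrix_rank(fit.model.exog) < k + 1:
        raise SingularDesignError("covariate collinear with factor dummies")
    tab = anova_lm(fit, typ=1)
    df_res = int(tab.loc["Residual", "df"])
    terms = [
        TermStat("factor", int(tab.loc["C(factor)", "df"]), df_res,
                 float(tab.loc["C(factor)", "F"]), float(tab.loc["C(factor)", "PR(>F)"])),
        TermStat("covariate", int(tab.loc["x", "df"]), df_res,
                 float(tab.loc["x", "F"]), float(tab.loc["x", "PR(>F)"])),
    ]
    coefs = {name: float(v) for name, v in fit.params.items()}
    return LinearFitResult(coefficients=coefs, terms=terms,
                           adjusted_r2=float(fit.rsquared_adj))


# ---------------------------------------------------------------------------
# diagnostics


def variance_homogeneity(values: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """Bartlett's test of equal group variances, by its closed form.

    K2 = [(N-k) ln s_p^2 - sum (n_i - 1) ln s_i^2] / C with the usual
    correction C; p from chi-square with k-1 df.
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [y[lab == g] for g in np.unique(lab)]
    k = len(groups)
    if k < 2:
        raise DesignError("variance homogeneity needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise DesignError("every group needs n >= 2")
    variances = [float(g.var(ddof=1)) for g in groups]
    if any(v == 0.0 for v in variances):
        raise DegenerateVarianceError("a group has zero sample variance")
    ni = np.array([g.size for g in groups], dtype=float)
    N = ni.sum()
    sp2 = float(np.sum((ni - 1) * np.array(variances)) / (N - k))
    k2_num = (N - k) * math.log(sp2) - float(
        np.sum((ni - 1) * np.log(np.array(variances)))
    )
    C = 1.0 + (float(np.sum(1.0 / (ni - 1))) - 1.0 / (N - k)) / (3.0 * (k - 1))
    k2 = k2_num / C
    p = float(stats.chi2.sf(k2, k - 1))
    return k2, p


def normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality check: returns (W, p)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)
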