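"""Stratified bootstrap of the recovery index with BCa intervals.

Resampling is stratified case resampling: each bootstrap replicate redraws,
with replacement and independently, within each of the three groups (control
t0, depleted t0, recovery t1), preserving the original group sizes, and
re-evaluates the recovery index on the resampled group means. The groups are
independent samples of different animals, so pooled resampling would mix
design cells.

Intervals are bias-corrected and accelerated (BCa): the percentile endpoints
are adjusted by a bias term z0, estimated from the fraction of replicates
below the plug-in estimate, and an acceleration term a, estimated by a
delete-one jackknife over the pooled observations (stratification
preserved). Replicates whose resampled denominator B = mean(control) -
mean(depleted) is non-positive leave the index undefined; they are excluded
and counted rather than clamped, so the tails are not distorted.

Two recovery indices are declared significantly different when their 95%
intervals do not overlap (a shared endpoint counts as overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import SemrecError, UnstableBaselineError
from .recovery import RecoveryIndexInput, compute_ri, ri_from_means

#: Quantile rule used everywhere: linear order-statistic interpolation.
QUANTILE_METHOD = "linear"

#: Maximum tolerated fraction of invalid (B <= 0) replicates.
MAX_INVALID_FRACTION = 0.20


@dataclass
class BcaInterval:
    low: float
    high: float
    z0: float
    a: float
    method: str  # "bca" | "percentile_fallback"


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the RI for one recovery cell."""

    replicates: np.ndarray      # valid RI replicates, %
    plug_in: float              # %, RI on the observed groups
    replicate_mean: float       # %
    ci_low: float
    ci_high: float
    z0: float
    a: float
    b: int                      # requested number of replications
    n_invalid: int              # replicates dropped for B <= 0
    seed: Optional[int]
    method: str                 # "bca" | "percentile_fallback"


def percentile_interval(
    replicates: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Plain percentile interval at alpha/2, 1 - alpha/2."""
    lo, hi = np.quantile(
        replicates, [alpha / 2.0, 1.0 - alpha / 2.0], method=QUANTILE_METHOD
    )
    return float(lo), float(hi)


def bca_interval(
    replicates: Sequence[float],
    plug_in: float,
    jackknife_values: Sequence[float],
    alpha: float = 0.05,
    z0: Optional[float] = None,
    a: Optional[float] = None,
) -> BcaInterval:
    """Bias-corrected accelerated interval from a bootstrap distribution.

    Parameters
    ----------
    replicates : bootstrap statistic values.
    plug_in : statistic on the original sample.
    jackknife_values : statistic with one observation deleted at a time
        (used for the acceleration term).
    alpha : two-sided miscoverage; 0.05 gives a 95% interval.
    z0, a : optional overrides for the bias-correction and acceleration
        terms (forcing both to 0 reduces BCa to the percentile interval,
        a useful oracle).
    """
    theta = np.asarray(replicates, dtype=float)
    if theta.size == 0:
        raise SemrecError("empty replicate vector")
    if np.ptp(theta) == 0.0:
        # Degenerate distribution: every resample gives the same value.
        return BcaInterval(plug_in, plug_in, 0.0, 0.0, "percentile_fallback")

    B = theta.size
    if z0 is None:
        prop = (np.sum(theta < plug_in) + 0.5 * np.sum(theta == plug_in)) / B
        prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
        z0 = float(stats.norm.ppf(prop))
    if a is None:
        jack = np.asarray(jackknife_values, dtype=float)
        d = jack.mean() - jack
        denom = 6.0 * np.sum(d**2) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0

    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)
    alpha1 = float(stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo))))
    alpha2 = float(stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi))))
    lo, hi = np.quantile(theta, [alpha1, alpha2], method=QUANTILE_METHOD)
    return BcaInterval(float(lo), float(hi), float(z0), float(a), "bca")


def jackknife_ri(inp: RecoveryIndexInput) -> np.ndarray:
    """Delete-one RI values across the pooled three-group sample.

    Each observation is deleted from its own group (grouped jackknife, the
    other two groups intact), matching the stratified functional.
    """
    groups = [
        np.asarray(inp.vdw_control_t0, float),
        np.asarray(inp.vdw_ee_t0, float),
        np.asarray(inp.vdw_ee_t1, float),
    ]
    means = [g.mean() for g in groups]
    out = []
    for gi, g in enumerate(groups):
        n = g.size
        if n < 2:
            raise SemrecError("jackknife needs n >= 2 in every group")
        # mean with element i removed: (n*mean - x_i) / (n-1)
        loo = (n * means[gi] - g) / (n - 1)
        for m_loo in loo:
            m = list(means)
            m[gi] = m_loo
            out.append(ri_from_means(m[0], m[1], m[2]))
    return np.asarray(out)


def bootstrap_ri(
    inp: RecoveryIndexInput,
    b: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Stratified case-resampling bootstrap of the recovery index.

    Deterministic for a fixed seed. Raises
    :class:`~semrec.errors.UnstableBaselineError` when more than 20% of
    replicates have a non-positive resampled denominator (the control and
    depleted groups are too close for the index to be estimated reliably).
    """
    groups = [
        np.asarray(inp.vdw_control_t0, float),
        np.asarray(inp.vdw_ee_t0, float),
        np.asarray(inp.vdw_ee_t1, float),
    ]
    for g in groups:
        if g.size < 2:
            raise SemrecError("bootstrap needs n >= 2 in every group")

    plug = compute_ri(inp).ri
    rng = np.random.default_rng(seed)
    boot_means = []
    for g in groups:
        idx = rng.integers(0, g.size, size=(b, g.size))
        boot_means.append(g[idx].mean(axis=1))
    m_c, m_e0, m_e1 = boot_means

    denom = m_c - m_e0
    valid = denom > 0
    n_invalid = int(b - valid.sum())
    if n_invalid > MAX_INVALID_FRACTION * b:
        raise UnstableBaselineError(
            f"{n_invalid}/{b} replicates had a non-positive denominator; "
            "control and depleted baselines are too close"
        )
    reps = (m_e1[valid] - m_e0[valid]) / denom[valid] * 100.0

    ci = bca_interval(reps, plug, jackknife_ri(inp), alpha=alpha)
    return BootstrapResult(
        replicates=reps,
        plug_in=plug,
        replicate_mean=float(reps.mean()),
        ci_low=ci.low,
        ci_high=ci.high,
        z0=ci.z0,
        a=ci.a,
        b=b,
        n_invalid=n_invalid,
        seed=seed,
        method=ci.method,
    )


def ris_differ(
    interval_a: tuple[float, float], interval_b: tuple[float, float]
) -> bool:
    """Non-overlap decision rule on two closed confidence intervals.

    True iff the intervals are disjoint; touching endpoints count as
    overlap, i.e. not significantly different.
    """
    (lo_a, hi_a), (lo_b, hi_b) = interval_a, interval_b
    if lo_a > hi_a or lo_b > hi_b:
        raise SemrecError("malformed interval (low > high)")
    return hi_a < lo_b or hi_b < lo_a
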