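"""Maximum likelihood, Fisher-information intervals, and parametric bootstrap.

The likelihood factorizes per parameter: lambda_1j has MLE n_1j / (T1 + T21)
and lambda_2j has MLE n_2j / T22, with observed-information variance
lambda_ij^2 / n_ij (the information matrix is diagonal). An MLE is undefined
when its failure count is zero; such entries are flagged as ``None`` rather
than raising, so simulation studies can count failed replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .model import PARAM_KEYS, RateParams, StepStressDataset, SufficientStats, sufficient_stats
from .simulate import simulate_dataset

__all__ = [
    "EstimateSet",
    "IntervalSet",
    "mle",
    "fisher_diag",
    "aci",
    "bootstrap_p",
    "bootstrap_t",
]

logger = logging.getLogger(__name__)

Key = tuple[int, int]


@dataclass(frozen=True)
class EstimateSet:
    """Four point estimates keyed by (stress, cause); ``None`` marks undefined."""

    method: str
    values: dict[Key, float | None]
    loss: str | None = None

    def __getitem__(self, key: Key) -> float | None:
        return self.values[key]

    def defined(self, key: Key) -> bool:
        return self.values[key] is not None

    @property
    def all_defined(self) -> bool:
        return all(v is not None for v in self.values.values())

    def as_params(self) -> RateParams:
        """Convert to RateParams (requires all four entries defined)."""
        if not self.all_defined:
            raise ValueError("estimate set has undefined entries")
        return RateParams(*(self.values[k] for k in PARAM_KEYS))


@dataclass(frozen=True)
class IntervalSet:
    """Four (lower, upper) interval bounds keyed by (stress, cause)."""

    method: str
    level: float
    bounds: dict[Key, tuple[float, float] | None]

    def __getitem__(self, key: Key) -> tuple[float, float] | None:
        return self.bounds[key]

    def width(self, key: Key) -> float | None:
        b = self.bounds[key]
        return None if b is None else b[1] - b[0]

    def covers(self, key: Key, value: float) -> bool | None:
        b = self.bounds[key]
        return None if b is None else bool(b[0] <= value <= b[1])


def mle(stats: SufficientStats) -> EstimateSet:
    """Maximum-likelihood estimates: n_1j/(T1+T21) and n_2j/T22."""
    values: dict[Key, float | None] = {}
    for i, j in PARAM_KEYS:
        n = stats.count(i, j)
        values[(i, j)] = n / stats.exposure(i) if n > 0 else None
    return EstimateSet(method="mle", values=values)


def fisher_diag(estimates: EstimateSet, stats: SufficientStats) -> dict[Key, float | None]:
    """Observed-information variances lambda_ij^2 / n_ij (diagonal matrix)."""
    out: dict[Key, float | None] = {}
    for key in PARAM_KEYS:
        lam = estimates[key]
        n = stats.count(*key)
        out[key] = None if lam is None else lam * lam / n
    return out


def aci(
    estimates: EstimateSet,
    stats: SufficientStats,
    level: float = 0.95,
    clip_at_zero: bool = False,
) -> IntervalSet:
    """Asymptotic normal confidence intervals lambda_hat +- z * lambda_hat/sqrt(n).

    Lower bounds are not truncated at zero by default (the asymptotic formula
    is symmetric); pass ``clip_at_zero=True`` to clip.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    variances = fisher_diag(estimates, stats)
    bounds: dict[Key, tuple[float, float] | None] = {}
    for key in PARAM_KEYS:
        lam, var = estimates[key], variances[key]
        if lam is None or var is None:
            bounds[key] = None
            continue
        half = z * math.sqrt(var)
        lo = lam - half
        bounds[key] = (max(0.0, lo) if clip_at_zero else lo, lam + half)
    return IntervalSet(method="aci", level=level, bounds=bounds)


def _order_stat_indices(B: int, level: float) -> tuple[int, int]:
    """1-based (ceil(B*g/2), ceil(B*(1-g/2))) order-statistic indices."""
    g = 1 - level
    # ceiling with float-noise forgiveness (B*g/2 may sit just above an integer)
    lo = max(1, math.ceil(B * g / 2 - 1e-9))
    hi = min(B, math.ceil(B * (1 - g / 2) - 1e-9))
    if lo >= hi:
        raise ValueError(f"B={B} too small for level {level}")
    return lo, hi


def _bootstrap_estimates(
    data: StepStressDataset, B: int, seed
) -> tuple[EstimateSet, SufficientStats, np.ndarray, np.ndarray, int]:
    """B parametric resamples refit by MLE; resamples with any zero count redrawn."""
    stats0 = sufficient_stats(data)
    est0 = mle(stats0)
    if not est0.all_defined:
        raise ValueError("MLE undefined on the observed data; cannot bootstrap")
    params0 = est0.as_params()
    rng = np.random.default_rng(seed)
    ests = np.empty((B, 4))
    ns = np.empty((B, 4))
    discarded = 0
    consecutive = 0
    b = 0
    while b < B:
        stats_b = sufficient_stats(simulate_dataset(params0, data.scheme, rng))
        if min(stats_b.counts) == 0:
            discarded += 1
            consecutive += 1
            if consecutive > 10 * B:
                raise RuntimeError(
                    f"bootstrap aborted: {consecutive} consecutive resamples had "
                    "an empty failure-count cell"
                )
            continue
        consecutive = 0
        est_b = mle(stats_b)
        ests[b] = [est_b[k] for k in PARAM_KEYS]
        ns[b] = stats_b.counts
        b += 1
    if discarded:
        logger.info("bootstrap: redrew %d resamples with an empty count cell", discarded)
    return est0, stats0, ests, ns, discarded


def bootstrap_p(
    data: StepStressDataset, B: int = 1000, level: float = 0.95, seed=0
) -> IntervalSet:
    """Percentile bootstrap: order statistics of the B refitted MLEs."""
    _, _, ests, _, _ = _bootstrap_estimates(data, B, seed)
    lo_i, hi_i = _order_stat_indices(B, level)
    srt = np.sort(ests, axis=0)
    bounds = {
        key: (float(srt[lo_i - 1, c]), float(srt[hi_i - 1, c]))
        for c, key in enumerate(PARAM_KEYS)
    }
    return IntervalSet(method="boot_p", level=level, bounds=bounds)


def bootstrap_t(
    data: StepStressDataset, B: int = 1000, level: float = 0.95, seed=0
) -> IntervalSet:
    """Studentized bootstrap using the observed-information standard error."""
    est0, stats0, ests, ns, _ = _bootstrap_estimates(data, B, seed)
    lo_i, hi_i = _order_stat_indices(B, level)
    lam0 = np.array([est0[k] for k in PARAM_KEYS])
    se0 = lam0 / np.sqrt([stats0.count(*k) for k in PARAM_KEYS])
    # studentize each resample by its own plug-in standard error
    tstat = np.sort((ests - lam0) / (ests / np.sqrt(ns)), axis=0)
    bounds = {
        key: (
            float(lam0[c] - tstat[hi_i - 1, c] * se0[c]),
            float(lam0[c] - tstat[lo_i - 1, c] * se0[c]),
        )
        for c, key in enumerate(PARAM_KEYS)
    }
    return IntervalSet(method="boot_t", level=level, bounds=bounds)
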