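"""Core model layer: domain types, distribution functions, sufficient statistics.

The experiment: ``n`` units start on stress level 1. Failures are observed
one at a time; at the *i*-th failure ``removals[i-1]`` surviving units are
withdrawn (progressive Type-II censoring). After the ``N1``-th failure the
stress is raised, and the test runs until ``N2`` further failures have been
observed. Each failure carries a cause label in {1, 2}; the two competing
causes act independently and lifetimes are exponential with cause- and
stress-specific rates ``lambda_ij`` (stress i, cause j). Stress levels are
linked by the cumulative exposure model, under which surviving units restart
memorylessly at the stage-2 rates when the stress changes.

All of the estimators in this package consume only the sufficient statistics
(n11, n12, n21, n22, T1, T21, T22) computed by :func:`sufficient_stats`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CensoringScheme",
    "StepStressDataset",
    "RateParams",
    "SufficientStats",
    "validate_scheme",
    "lifetime_cdf",
    "lifetime_pdf",
    "cause_density",
    "cem_shift",
    "sufficient_stats",
    "PARAM_KEYS",
]

#: Canonical ordering of the four rate parameters, keyed (stress, cause).
PARAM_KEYS: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1), (2, 2))


@dataclass(frozen=True)
class CensoringScheme:
    """Progressive Type-II censoring design for a two-stage step-stress test.

    Parameters
    ----------
    n : total number of units placed on test.
    N1, N2 : number of failures to observe at stress levels 1 and 2.
    removals : R_1..R_{N1+N2}, units withdrawn at each observed failure.
        Accounting must balance: ``N1 + N2 + sum(removals) == n``.
    """

    n: int
    N1: int
    N2: int
    removals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "removals", tuple(int(r) for r in self.removals))

    @property
    def total_failures(self) -> int:
        return self.N1 + self.N2


def validate_scheme(scheme: CensoringScheme) -> CensoringScheme:
    """Check the accounting identities of a censoring scheme.

    Returns the scheme unchanged when valid; raises ``ValueError`` naming the
    violated identity otherwise.
    """
    if scheme.N1 < 1 or scheme.N2 < 1:
        raise ValueError(
            f"both stages need at least one failure, got N1={scheme.N1}, N2={scheme.N2}"
        )
    if len(scheme.removals) != scheme.total_failures:
        raise ValueError(
            f"expected {scheme.total_failures} removal counts, got {len(scheme.removals)}"
        )
    if any(r < 0 for r in scheme.removals):
        raise ValueError("removal counts must be nonnegative")
    total = scheme.N1 + scheme.N2 + sum(scheme.removals)
    if total != scheme.n:
        raise ValueError(
            f"accounting violation: N1+N2+sum(R) = {total} != n = {scheme.n} "
            f"(deficit {scheme.n - total})"
        )
    # every failure must have a unit available: at-risk count before failure i
    # is n - (i-1) - cumulative removals, and must stay >= 1
    at_risk = scheme.n
    for i, r in enumerate(scheme.removals, start=1):
        if at_risk < 1:
            raise ValueError(f"at-risk count exhausted before failure {i}")
        at_risk -= 1 + r
    return scheme


@dataclass(frozen=True)
class RateParams:
    """The four exponential hazard rates lambda_ij (stress i, cause j)."""

    lambda11: float
    lambda12: float
    lambda21: float
    lambda22: float

    def __post_init__(self) -> None:
        for key in PARAM_KEYS:
            if not self[key] > 0:
                raise ValueError(f"rate lambda{key[0]}{key[1]} must be positive")

    def __getitem__(self, key: tuple[int, int]) -> float:
        i, j = key
        return getattr(self, f"lambda{i}{j}")

    def stage_rate(self, stage: int) -> float:
        """Total hazard rate at a stress level: lambda_i1 + lambda_i2."""
        return self[(stage, 1)] + self[(stage, 2)]

    def cause_prob(self, stage: int, cause: int = 1) -> float:
        """Probability that a failure at the given stage is due to `cause`."""
        return self[(stage, cause)] / self.stage_rate(stage)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.lambda11, self.lambda12, self.lambda21, self.lambda22)


@dataclass(frozen=True)
class StepStressDataset:
    """Observed step-stress competing-risks data under progressive censoring.

    ``times`` are the ordered failure times, ``causes`` the matching cause
    labels. The stress-change time ``tau`` is the ``N1``-th observed failure
    time (the stress is raised when the N1-th failure occurs).
    """

    scheme: CensoringScheme
    times: tuple[float, ...]
    causes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "causes", tuple(int(c) for c in self.causes))
        validate_scheme(self.scheme)
        m = self.scheme.total_failures
        if len(self.times) != m or len(self.causes) != m:
            raise ValueError(
                f"expected {m} failure records, got {len(self.times)} times "
                f"and {len(self.causes)} causes"
            )
        if any(c not in (1, 2) for c in self.causes):
            raise ValueError("cause labels must be 1 or 2")
        if self.times[0] <= 0:
            raise ValueError("failure times must be positive")
        diffs = np.diff(self.times)
        if np.any(diffs < 0):
            raise ValueError("failure times must be nondecreasing")
        if np.any(diffs == 0):
            warnings.warn(
                "tied failure times: ties have probability zero under the "
                "exponential model",
                stacklevel=2,
            )

    @property
    def tau(self) -> float:
        """Stress-change time: the N1-th observed failure time."""
        return self.times[self.scheme.N1 - 1]


@dataclass(frozen=True)
class SufficientStats:
    """Counts and exposures that determine every estimator in this package.

    ``n_ij`` count failures by stress level and cause. ``T1`` is the
    removal-weighted stage-1 exposure of units that exited during stage 1,
    ``T21`` the exposure accrued at stress 1 (up to tau) by units that
    survived into stage 2, and ``T22`` the removal-weighted stage-2 exposure
    beyond tau. ``T1 + T21`` is the total time on test at stress 1 and
    ``T22`` the total time on test at stress 2.
    """

    n11: int
    n12: int
    n21: int
    n22: int
    T1: float
    T21: float
    T22: float

    def count(self, stage: int, cause: int) -> int:
        return int(getattr(self, f"n{stage}{cause}"))

    def exposure(self, stage: int) -> float:
        """Total time on test at the given stress level."""
        return self.T1 + self.T21 if stage == 1 else self.T22

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)


def _check_time(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def lifetime_cdf(t, params: RateParams, tau: float):
    """CDF of the observed lifetime T = min(T1, T2) under the step-stress model.

    F(t) = 1 - exp(-theta1 t) for t <= tau and
    F(t) = 1 - exp(-(theta1 - theta2) tau - theta2 t) for t > tau,
    where theta_i = lambda_i1 + lambda_i2. Continuous at tau by construction
    (the cumulative exposure model matches the accumulated hazard there).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = _check_time(t)
    th1, th2 = params.stage_rate(1), params.stage_rate(2)
    cum_haz = np.where(t <= tau, th1 * t, (th1 - th2) * tau + th2 * t)
    out = -np.expm1(-cum_haz)
    return out if out.ndim else float(out)


def lifetime_pdf(t, params: RateParams, tau: float):
    """Marginal density of the observed lifetime (sum of the cause densities)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = _check_time(t)
    th1, th2 = params.stage_rate(1), params.stage_rate(2)
    rate = np.where(t <= tau, th1, th2)
    cum_haz = np.where(t <= tau, th1 * t, (th1 - th2) * tau + th2 * t)
    out = rate * np.exp(-cum_haz)
    return out if out.ndim else float(out)


def cause_density(t, cause: int, params: RateParams, tau: float):
    """Joint density f(t, cause) of failure time and cause label.

    f(t, j) = lambda_{1j} exp(-theta1 t) for t <= tau and
    lambda_{2j} exp(-(theta1 - theta2) tau - theta2 t) beyond tau. Summing
    over j recovers :func:`lifetime_pdf`.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = _check_time(t)
    th1, th2 = params.stage_rate(1), params.stage_rate(2)
    lam = np.where(t <= tau, params[(1, cause)], params[(2, cause)])
    cum_haz = np.where(t <= tau, th1 * t, (th1 - th2) * tau + th2 * t)
    out = lam * np.exp(-cum_haz)
    return out if out.ndim else float(out)


def cem_shift(cause: int, params: RateParams, tau: float) -> float:
    """Cumulative-exposure time shift a_j = (1 - lambda_1j/lambda_2j) tau.

    The stage-2 lifetime distribution for cause j, shifted by a_j, matches
    the stage-1 distribution at tau: F_1j(tau) = F_2j(tau - a_j).
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return (1.0 - params[(1, cause)] / params[(2, cause)]) * tau


def sufficient_stats(data: StepStressDataset) -> SufficientStats:
    """Reduce a dataset to the sufficient statistics of the likelihood.

    T1  = sum_{i<=N1} (1+R_i) t_i
    T21 = tau * sum_{i>N1} (1+R_i)
    T22 = sum_{i>N1} (1+R_i) (t_i - tau)
    """
    N1 = data.scheme.N1
    t = np.asarray(data.times)
    w = 1.0 + np.asarray(data.scheme.removals, dtype=float)
    c = np.asarray(data.causes)
    tau = data.tau
    n11 = int(np.sum(c[:N1] == 1))
    n21 = int(np.sum(c[N1:] == 1))
    return SufficientStats(
        n11=n11,
        n12=N1 - n11,
        n21=n21,
        n22=data.scheme.N2 - n21,
        T1=float(np.sum(w[:N1] * t[:N1])),
        T21=float(tau * np.sum(w[N1:])),
        T22=float(np.sum(w[N1:] * (t[N1:] - tau))),
    )
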