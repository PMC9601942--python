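"""E-Bayesian estimation: conjugate Bayes estimators averaged over hyperpriors.

The gamma hyperparameters (alpha, beta) are given a hyperprior on the box
(0,1) x (0,c): either uniform, pi(alpha, beta) = 1/c, or linear-in-beta,
pi(alpha, beta) = 2 beta / c^2 (more weight on larger beta, i.e. thinner
prior tails). The E-Bayes estimate is the expectation of the conjugate Bayes
point estimator over that hyperprior, which has a closed form for every loss.

With n the failure count, E the matching stage exposure and c the beta bound
(closed forms below write T for E):

* SELF, uniform:  (2n+1)/(2c) ln(1 + c/T)
* SELF, linear:   (2n+1)/c^2 (c - T ln(1 + c/T))
* ELF: same with coefficient (2n-1)
* LINEX: coefficient/(2k) times the hyperprior mean of ln(1 + k/(beta+T)),
  with coefficient (2n+1) under the ``corrected`` dialect and (2n-1) under
  ``paper_literal`` (mirroring the conjugate-Bayes dialect switch).

``ebayes_sample`` draws from the corresponding prior-mixture posterior
(draw hyperparameters from the hyperprior, then lambda from the conditional
gamma posterior); feeding those draws to the interval helpers in
:mod:`stepstress.bayes` yields E-Bayes credible intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bayes import LossSpec
from .frequentist import EstimateSet
from .model import PARAM_KEYS, SufficientStats

__all__ = ["HyperPrior", "ebayes_estimate", "ebayes_sample"]

Key = tuple[int, int]

FAMILIES = ("uniform", "linear")


@dataclass(frozen=True)
class HyperPrior:
    """Hyperprior on (alpha, beta) over (0,1) x (0,c): uniform or linear in beta."""

    c: float
    family: str = "uniform"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("hyperparameter bound c must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    def sample_hyperparams(self, N: int, rng: np.random.Generator):
        """Draw (alpha, beta) pairs; linear family uses beta = c * sqrt(U)."""
        alpha = rng.random(N)
        u = rng.random(N)
        beta = self.c * np.sqrt(u) if self.family == "linear" else self.c * u
        return alpha, beta


def _mean_inv_rate(T: float, c: float, family: str) -> float:
    """Hyperprior mean of 1/(beta + T)."""
    if family == "uniform":
        return math.log1p(c / T) / c
    return 2.0 / (c * c) * (c - T * math.log1p(c / T))


def _mean_log_linex(T: float, c: float, k: float, family: str) -> float:
    """Hyperprior mean of ln(1 + k/(beta + T))."""
    if 1 + k / T <= 0 or 1 + k / (c + T) <= 0:
        raise ValueError(f"LINEX curvature k={k} outside domain for exposure T={T}")
    if family == "uniform":
        return (
            (c + T + k) * math.log(c + T + k)
            - (T + k) * math.log(T + k)
            - (c + T) * math.log(c + T)
            + T * math.log(T)
        ) / c
    return (
        math.log1p(k / (c + T))
        - (T + k) ** 2 / (c * c) * math.log1p(c / (T + k))
        + T * T / (c * c) * math.log1p(c / T)
        + k / c
    )


def _ebayes_point(
    n: int, T: float, hyper: HyperPrior, loss: LossSpec, dialect: str
) -> float | None:
    if loss.loss == "self":
        return (n + 0.5) * _mean_inv_rate(T, hyper.c, hyper.family)
    if loss.loss == "elf":
        if n < 1:
            return None
        return (n - 0.5) * _mean_inv_rate(T, hyper.c, hyper.family)
    coeff = n + 0.5 if dialect == "corrected" else n - 0.5  # linex
    if dialect == "paper_literal" and n < 1:
        return None
    return (coeff / loss.k) * _mean_log_linex(T, hyper.c, loss.k, hyper.family)


def ebayes_estimate(
    stats: SufficientStats,
    hyper: HyperPrior,
    loss: LossSpec = LossSpec(),
    dialect: str = "corrected",
) -> EstimateSet:
    """Closed-form E-Bayes point estimates for the four rates."""
    if dialect not in ("corrected", "paper_literal"):
        raise ValueError("dialect must be 'corrected' or 'paper_literal'")
    values: dict[Key, float | None] = {
        (i, j): _ebayes_point(stats.count(i, j), stats.exposure(i), hyper, loss, dialect)
        for i, j in PARAM_KEYS
    }
    return EstimateSet(method="ebayes", loss=loss.loss, values=values)


def ebayes_sample(
    stats: SufficientStats, hyper: HyperPrior, N: int = 1000, seed=0
) -> dict[Key, np.ndarray]:
    """Draws from the hyperprior mixture of conjugate posteriors.

    For each draw: (alpha, beta) from the hyperprior, then
    lambda ~ Gamma(n + alpha, beta + exposure). The sample mean converges to
    the SELF E-Bayes closed form.
    """
    if N < 100:
        raise ValueError("N must be >= 100")
    rng = np.random.default_rng(seed)
    out: dict[Key, np.ndarray] = {}
    for i, j in PARAM_KEYS:
        alpha, beta = hyper.sample_hyperparams(N, rng)
        out[(i, j)] = rng.gamma(stats.count(i, j) + alpha, 1.0 / (beta + stats.exposure(i)))
    return out
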