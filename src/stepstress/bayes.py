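"""Conjugate gamma Bayes: posteriors, point estimators, credible intervals.

Each rate lambda_ij gets an independent Gamma(alpha_ij, beta_ij) prior
(shape, rate). The posterior is Gamma(n_ij + alpha_ij, beta_ij + E_i) where
E_1 = T1 + T21 and E_2 = T22. Point estimators under the three losses:

* squared error (SELF):  posterior mean (n + a) / (b + E)
* entropy (ELF):         1 / E[1/lambda] = (n + a - 1) / (b + E)
* LINEX with curvature k: -(1/k) ln E[exp(-k lambda)]
                          = ((n + a) / k) ln(1 + k / (b + E))

The printed closed form for the LINEX case carries coefficient (n + a - 1)
instead of the (n + a) that the gamma Laplace transform yields; the
``dialect`` switch selects ``"corrected"`` (default) or ``"paper_literal"``.

Because the posterior is a known gamma, "posterior sampling" is exact i.i.d.
gamma sampling; no Markov chain is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .frequentist import EstimateSet
from .model import PARAM_KEYS, SufficientStats

__all__ = [
    "GammaPrior",
    "LossSpec",
    "PosteriorSet",
    "posterior_params",
    "bayes_estimate",
    "posterior_sample",
    "equal_tail_cri",
    "hpd_interval",
    "gamma_point_estimate",
]

Key = tuple[int, int]

LOSSES = ("self", "elf", "linex")
DIALECTS = ("corrected", "paper_literal")


@dataclass(frozen=True)
class LossSpec:
    """Loss function choice; ``k`` is the LINEX curvature (required iff linex)."""

    loss: str = "self"
    k: float | None = None

    def __post_init__(self) -> None:
        loss = self.loss.lower()
        object.__setattr__(self, "loss", loss)
        if loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {loss!r}")
        if loss == "linex":
            if self.k is None or self.k == 0:
                raise ValueError("LINEX loss requires a nonzero curvature k")
        elif self.k is not None:
            raise ValueError(f"k is only meaningful for LINEX loss, got k={self.k}")


@dataclass(frozen=True)
class GammaPrior:
    """Independent Gamma(shape alpha_ij, rate beta_ij) priors for the four rates."""

    alpha: dict[Key, float]
    beta: dict[Key, float]

    def __post_init__(self) -> None:
        for key in PARAM_KEYS:
            if key not in self.alpha or key not in self.beta:
                raise ValueError(f"prior missing hyperparameters for {key}")
            if self.alpha[key] <= 0 or self.beta[key] <= 0:
                raise ValueError(f"hyperparameters for {key} must be positive")

    @classmethod
    def constant(cls, alpha: float, beta: float) -> "GammaPrior":
        """Same (alpha, beta) for all four parameters."""
        return cls(
            alpha={k: float(alpha) for k in PARAM_KEYS},
            beta={k: float(beta) for k in PARAM_KEYS},
        )


@dataclass(frozen=True)
class PosteriorSet:
    """Gamma(shape, rate) posterior parameters keyed by (stress, cause)."""

    params: dict[Key, tuple[float, float]]

    def __getitem__(self, key: Key) -> tuple[float, float]:
        return self.params[key]


def posterior_params(stats: SufficientStats, prior: GammaPrior) -> PosteriorSet:
    """Conjugate update: Gamma(n_ij + alpha_ij, beta_ij + exposure(stage i))."""
    return PosteriorSet(
        params={
            (i, j): (
                stats.count(i, j) + prior.alpha[(i, j)],
                prior.beta[(i, j)] + stats.exposure(i),
            )
            for i, j in PARAM_KEYS
        }
    )


def gamma_point_estimate(
    shape: float, rate: float, loss: LossSpec, dialect: str = "corrected"
) -> float | None:
    """Point estimator of a Gamma(shape, rate) posterior under the given loss.

    Returns ``None`` (undefined) for the entropy loss when shape <= 1, where
    the posterior mean of 1/lambda does not exist.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    if loss.loss == "self":
        return shape / rate
    if loss.loss == "elf":
        return (shape - 1) / rate if shape > 1 else None
    k = float(loss.k)  # linex
    if 1 + k / rate <= 0:
        raise ValueError(f"LINEX curvature k={k} outside posterior domain (rate={rate})")
    coeff = shape if dialect == "corrected" else shape - 1
    return (coeff / k) * math.log1p(k / rate)


def bayes_estimate(
    stats: SufficientStats,
    prior: GammaPrior,
    loss: LossSpec = LossSpec(),
    dialect: str = "corrected",
) -> EstimateSet:
    """Bayes point estimates for the four rates under the chosen loss."""
    post = posterior_params(stats, prior)
    values: dict[Key, float | None] = {
        key: gamma_point_estimate(*post[key], loss, dialect) for key in PARAM_KEYS
    }
    return EstimateSet(method="bayes", loss=loss.loss, values=values)


def posterior_sample(
    posterior: PosteriorSet, N: int = 1000, seed=0
) -> dict[Key, np.ndarray]:
    """N exact i.i.d. draws from each marginal gamma posterior."""
    if N < 100:
        raise ValueError("N must be >= 100 for stable interval estimates")
    rng = np.random.default_rng(seed)
    return {
        key: rng.gamma(shape, 1.0 / rate, size=N)
        for key, (shape, rate) in ((k, posterior[k]) for k in PARAM_KEYS)
    }


def _ceil(x: float) -> int:
    """Ceiling that forgives float noise just above an integer."""
    return math.ceil(x - 1e-9)


def _sorted_draws(draws: np.ndarray) -> np.ndarray:
    arr = np.sort(np.asarray(draws, dtype=float))
    if arr.size == 0:
        raise ValueError("draws must be nonempty")
    return arr


def equal_tail_cri(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail credible interval from posterior draws.

    Endpoints are the ceil(N*g/2)-th and ceil(N*(1-g/2))-th order statistics
    (1-based), g = 1 - level.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    arr = _sorted_draws(draws)
    N = arr.size
    g = 1 - level
    if N * g / 2 < 1:
        raise ValueError(f"sample of {N} too small for level {level}")
    lo = _ceil(N * g / 2)
    hi = _ceil(N * (1 - g / 2))
    return float(arr[lo - 1]), float(arr[hi - 1])


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval by the minimal-width window sweep.

    Among the fixed-coverage windows (x_[m], x_[m + ceil(level*N)]) for
    m = 1..N - ceil(level*N), return the narrowest; ties break toward the
    smallest m.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    arr = _sorted_draws(draws)
    N = arr.size
    h = _ceil(level * N)
    if h >= N:
        raise ValueError(f"sample of {N} too small for level {level}")
    widths = arr[h:] - arr[: N - h]
    m_star = int(np.argmin(widths))  # argmin returns the first minimum: smallest m
    return float(arr[m_star]), float(arr[m_star + h])
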