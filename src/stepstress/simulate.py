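"""Exact simulation of progressively censored step-stress competing-risks data.

The sampler exploits exponential memorylessness: with ``m`` units at risk at
total stage rate ``theta``, the waiting time to the next failure is
Exponential(m * theta), the failing unit's cause is 1 with probability
``lambda_i1 / theta`` independently of the waiting time, and progressively
removed survivors are exchangeable with the rest, so no unit identities need
tracking. Under the cumulative exposure model with exponential margins, the
units surviving the stress change restart memorylessly at the stage-2 rates.
This makes the gap-rate construction exact and O(N1 + N2) per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .model import CensoringScheme, RateParams, StepStressDataset, validate_scheme

__all__ = ["SimConfig", "simulate_dataset", "simulate_many"]


@dataclass(frozen=True)
class SimConfig:
    """A replicated-simulation configuration."""

    params: RateParams
    scheme: CensoringScheme
    seed: int
    replications: int = 1

    def __post_init__(self) -> None:
        validate_scheme(self.scheme)
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_dataset(
    params: RateParams, scheme: CensoringScheme, seed
) -> StepStressDataset:
    """Draw one progressively Type-II censored step-stress dataset.

    ``seed`` may be an integer, a ``SeedSequence``, or a ``Generator``;
    identical (params, scheme, seed) triples give identical datasets.
    """
    validate_scheme(scheme)
    rng = _as_rng(seed)
    removals = np.asarray(scheme.removals)
    # at-risk count just before each failure
    exits = np.concatenate(([0], np.cumsum(1 + removals)[:-1]))
    at_risk = scheme.n - exits
    if np.any(at_risk < 1):
        raise ValueError("scheme infeasible: at-risk count exhausted")

    N1, N2 = scheme.N1, scheme.N2
    th1, th2 = params.stage_rate(1), params.stage_rate(2)
    rates = np.concatenate((np.full(N1, th1), np.full(N2, th2))) * at_risk
    gaps = rng.exponential(1.0 / rates)
    times = np.cumsum(gaps)

    p1 = np.concatenate(
        (np.full(N1, params.cause_prob(1)), np.full(N2, params.cause_prob(2)))
    )
    causes = np.where(rng.random(N1 + N2) < p1, 1, 2)
    return StepStressDataset(scheme=scheme, times=tuple(times), causes=tuple(causes))


def child_seed(seed: int, replication: int) -> np.random.SeedSequence:
    """Deterministic, collision-free per-replication seed."""
    return np.random.SeedSequence(entropy=(int(seed), int(replication)))


def simulate_many(config: SimConfig) -> Iterator[StepStressDataset]:
    """Yield ``config.replications`` independent datasets.

    Replication r (1-based) uses a child seed derived from (seed, r), so the
    stream is independent of iteration order and free of collisions.
    """
    for r in range(1, config.replications + 1):
        yield simulate_dataset(
            config.params, config.scheme, np.random.default_rng(child_seed(config.seed, r))
        )
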