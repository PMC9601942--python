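"""Monte-Carlo study driver: average estimates, MSE, interval length, coverage.

Replicates the simulation-study workflow: generate progressively censored
step-stress datasets at known true rates, apply the requested estimators and
interval methods to each, and summarize per (scheme, method, loss, family,
parameter) cell as

    AE  = mean of the estimates over replications,
    MSE = mean of (true - estimate)^2,
    AL  = mean interval width,
    CP  = fraction of intervals covering the true rate.

Replicates on which a method is undefined (an empty failure-count cell) are
excluded from that method's averages and counted in the diagnostics.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import (
    GammaPrior,
    LossSpec,
    bayes_estimate,
    equal_tail_cri,
    hpd_interval,
    posterior_params,
    posterior_sample,
)
from .ebayes import HyperPrior, ebayes_estimate, ebayes_sample
from .frequentist import aci, bootstrap_p, bootstrap_t, mle
from .hbayes import QuadratureSpec, hbayes_estimate, hbayes_sample
from .model import PARAM_KEYS, CensoringScheme, RateParams, sufficient_stats
from .simulate import child_seed, simulate_dataset

__all__ = ["StudyConfig", "StudyResult", "run_study", "render_tables"]

logger = logging.getLogger(__name__)

POINT_METHODS = ("mle", "bayes", "ebayes", "hbayes")
INTERVAL_METHODS = ("aci", "boot_p", "boot_t", "bayes_eqt", "bayes_hpd", "ebayes_hpd", "hbayes_hpd")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a Monte-Carlo comparison study.

    Defaults mirror the reference study conditions: true rates (2, 1, 4, 2),
    1000 replications, hyperparameter bound c = 0.2, LINEX curvature k = 4,
    95% intervals, and a diffuse Gamma(0.5, 0.1) prior for the plain-Bayes
    columns (which any conjugate analysis needs but is otherwise arbitrary).
    """

    params: RateParams = RateParams(2.0, 1.0, 4.0, 2.0)
    schemes: Sequence[CensoringScheme] = ()
    replications: int = 1000
    methods: Sequence[str] = POINT_METHODS
    losses: Sequence[LossSpec] = (LossSpec("self"),)
    families: Sequence[str] = ("uniform", "linear")
    intervals: Sequence[str] = ()
    prior: GammaPrior = field(default_factory=lambda: GammaPrior.constant(0.5, 0.1))
    c: float = 0.2
    k: float = 4.0
    B: int = 1000
    N: int = 1000
    level: float = 0.95
    seed: int = 0
    dialect: str = "corrected"
    quad: QuadratureSpec = QuadratureSpec()

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        for m in self.methods:
            if m not in POINT_METHODS:
                raise ValueError(f"unknown method {m!r}")
        for m in self.intervals:
            if m not in INTERVAL_METHODS:
                raise ValueError(f"unknown interval method {m!r}")


@dataclass
class StudyResult:
    """Long-format summaries: one row per (scheme, method, ..., parameter) cell."""

    points: pd.DataFrame  # scheme, method, loss, family, param, AE, MSE, n_used, n_undefined
    intervals: pd.DataFrame  # scheme, method, family, param, AL, CP, n_used
    config: StudyConfig


def _param_label(key) -> str:
    return f"lambda{key[0]}{key[1]}"


def _point_estimators(config: StudyConfig):
    """Yield (method, loss, family, callable(stats) -> EstimateSet)."""
    for loss in config.losses:
        if "mle" in config.methods and loss.loss == "self":
            yield "mle", None, None, lambda s: mle(s)
        if "bayes" in config.methods:
            yield "bayes", loss.loss, None, (
                lambda s, lo=loss: bayes_estimate(s, config.prior, lo, config.dialect)
            )
        for family in config.families:
            hyper = HyperPrior(c=config.c, family=family)
            if "ebayes" in config.methods:
                yield "ebayes", loss.loss, family, (
                    lambda s, lo=loss, h=hyper: ebayes_estimate(s, h, lo, config.dialect)
                )
            if "hbayes" in config.methods:
                yield "hbayes", loss.loss, family, (
                    lambda s, lo=loss, h=hyper: hbayes_estimate(
                        s, h, lo, config.quad, config.dialect
                    )
                )


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full Monte-Carlo study described by ``config``."""
    point_rows = []
    interval_rows = []
    truth = {key: config.params[key] for key in PARAM_KEYS}

    for s_idx, scheme in enumerate(config.schemes):
        estimators = list(_point_estimators(config))
        est_acc = {e[:3]: {k: [] for k in PARAM_KEYS} for e in estimators}
        undef = {e[:3]: 0 for e in estimators}
        # aci/boot_*/bayes_* intervals have no family; the E-/H-Bayes HPD
        # intervals run once per hyperprior family
        iv_acc = {}
        for m in config.intervals:
            fams = config.families if m in ("ebayes_hpd", "hbayes_hpd") else (None,)
            for fam in fams:
                iv_acc[(m, fam)] = {k: [] for k in PARAM_KEYS}

        for r in range(1, config.replications + 1):
            rng = np.random.default_rng(child_seed(config.seed + 1000 * s_idx, r))
            data = simulate_dataset(config.params, scheme, rng)
            stats = sufficient_stats(data)

            for method, loss, family, fn in estimators:
                est = fn(stats)
                if not est.all_defined:
                    undef[(method, loss, family)] += 1
                    continue
                for key in PARAM_KEYS:
                    est_acc[(method, loss, family)][key].append(est[key])

            for (m, fam), acc in iv_acc.items():
                ivs = _intervals_for(m, fam, data, stats, config, rng)
                if ivs is None:
                    continue
                for key in PARAM_KEYS:
                    b = ivs[key]
                    if b is not None:
                        acc[key].append((b[1] - b[0], b[0] <= truth[key] <= b[1]))

        for (method, loss, family), acc in est_acc.items():
            for key in PARAM_KEYS:
                vals = np.asarray(acc[key])
                n_used = vals.size
                point_rows.append(
                    {
                        "scheme": s_idx + 1,
                        "n": scheme.n,
                        "N1": scheme.N1,
                        "N2": scheme.N2,
                        "method": method,
                        "loss": loss,
                        "family": family,
                        "param": _param_label(key),
                        "AE": float(vals.mean()) if n_used else np.nan,
                        "MSE": float(np.mean((truth[key] - vals) ** 2)) if n_used else np.nan,
                        "n_used": n_used,
                        "n_undefined": undef[(method, loss, family)],
                    }
                )
        for (m, fam), acc in iv_acc.items():
            for key in PARAM_KEYS:
                arr = np.asarray(acc[key], dtype=float)
                n_used = len(acc[key])
                interval_rows.append(
                    {
                        "scheme": s_idx + 1,
                        "n": scheme.n,
                        "N1": scheme.N1,
                        "N2": scheme.N2,
                        "method": m,
                        "family": fam,
                        "param": _param_label(key),
                        "AL": float(arr[:, 0].mean()) if n_used else np.nan,
                        "CP": float(arr[:, 1].mean()) if n_used else np.nan,
                        "n_used": n_used,
                    }
                )
        logger.info("scheme %d/%d done", s_idx + 1, len(list(config.schemes)))

    return StudyResult(
        points=pd.DataFrame(point_rows),
        intervals=pd.DataFrame(interval_rows),
        config=config,
    )


def _intervals_for(method, family, data, stats, config, rng):
    """Compute one replicate's intervals for one method; None if undefined."""
    est = mle(stats)
    if method == "aci":
        return aci(est, stats, config.level) if est.all_defined else None
    if method in ("boot_p", "boot_t"):
        if not est.all_defined:
            return None
        fn = bootstrap_p if method == "boot_p" else bootstrap_t
        try:
            return fn(data, config.B, config.level, rng)
        except RuntimeError:
            return None
    if method in ("bayes_eqt", "bayes_hpd"):
        draws = posterior_sample(posterior_params(stats, config.prior), config.N, rng)
        pick = equal_tail_cri if method == "bayes_eqt" else hpd_interval
        return _IntervalDict({k: pick(draws[k], config.level) for k in PARAM_KEYS})
    hyper = HyperPrior(c=config.c, family=family)
    if method == "ebayes_hpd":
        draws = ebayes_sample(stats, hyper, config.N, rng)
    else:  # hbayes_hpd
        draws = hbayes_sample(stats, hyper, config.N, rng, config.dialect)
    return _IntervalDict({k: hpd_interval(draws[k], config.level) for k in PARAM_KEYS})


class _IntervalDict(dict):
    """Adapter so dict-of-bounds supports the IntervalSet item protocol."""

    def __getitem__(self, key):
        return dict.__getitem__(self, key)


def render_tables(result: StudyResult) -> dict[str, str]:
    """Render the study as tab-separated tables, one per parameter and metric.

    Keys are like ``"points_lambda11"`` / ``"intervals_lambda11"``; values are
    TSV text with AE/MSE (or AL/CP) rounded to 4 decimals. Parsing a rendered
    table recovers the values to that precision.
    """
    out: dict[str, str] = {}
    for key in PARAM_KEYS:
        label = _param_label(key)
        pts = result.points[result.points["param"] == label]
        if len(pts):
            tbl = pts[["scheme", "n", "N1", "N2", "method", "loss", "family", "AE", "MSE"]].copy()
            tbl[["AE", "MSE"]] = tbl[["AE", "MSE"]].round(4)
            out[f"points_{label}"] = tbl.to_csv(sep="\t", index=False)
        ivs = result.intervals[result.intervals["param"] == label] if len(result.intervals) else None
        if ivs is not None and len(ivs):
            tbl = ivs[["scheme", "n", "N1", "N2", "method", "family", "AL", "CP"]].copy()
            tbl[["AL", "CP"]] = tbl[["AL", "CP"]].round(4)
            out[f"intervals_{label}"] = tbl.to_csv(sep="\t", index=False)
    if not out:
        # empty result: still emit a header-only points table
        out["points"] = "scheme\tn\tN1\tN2\tmethod\tloss\tfamily\tAE\tMSE\n"
    return out
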