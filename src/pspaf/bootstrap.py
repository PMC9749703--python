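"""Bootstrap standard errors and confidence intervals.

All inference in this package is bootstrap-based: the estimators are smooth
plug-in functionals of fitted nuisance models, and analytic standard errors
combining the mediator and outcome models are not available.  Each replicate
resamples records (stratified by case status for case-control designs,
preserving the case and control counts exactly), recomputes the design
weights from the study design, refits every nuisance model and re-evaluates
the estimator.  The default interval is the normal approximation
``estimate +/- 1.96 * SE``; percentile intervals are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm

from .data import StudyDataset
from .estimators import PAFResult
from .exceptions import ConfigurationError, InferenceError, PSPAFError

logger = logging.getLogger("pspaf")

__all__ = ["BootstrapConfig", "bootstrap_estimate"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``stratified=None`` resolves to stratified (by case status) for
    case-control designs and unstratified otherwise.  Per-replicate random
    streams are spawned from the master seed by counter
    (``SeedSequence(seed).spawn(n_boot)``), so replicates are mutually
    independent and the whole run is reproducible bit-for-bit.
    """

    n_boot: int = 200
    seed: int = 0
    stratified: bool | None = None
    ci: str = "normal"  # "normal" | "percentile"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ConfigurationError("n_boot must be >= 2")
        if self.ci not in ("normal", "percentile"):
            raise ConfigurationError(f"unknown CI type {self.ci!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must lie in (0, 1)")


def _resample_indices(dataset: StudyDataset, stratified: bool, rng) -> np.ndarray:
    n = dataset.n
    if not stratified:
        return rng.integers(0, n, size=n)
    y = dataset.y
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    take_cases = case_idx[rng.integers(0, len(case_idx), size=len(case_idx))]
    take_ctrls = ctrl_idx[rng.integers(0, len(ctrl_idx), size=len(ctrl_idx))]
    return np.concatenate([take_cases, take_ctrls])


def bootstrap_estimate(dataset: StudyDataset,
                       pipeline: Callable[[StudyDataset], Mapping[str, float] | float],
                       config: BootstrapConfig = BootstrapConfig(),
                       ) -> dict[str, PAFResult]:
    """Point estimates with bootstrap SEs and CIs.

    ``pipeline`` receives a (re)sampled dataset, refits all nuisance models
    on it and returns either a single estimate or a mapping of estimand
    labels to estimates.  Replicates in which any model fails to converge are
    dropped and counted; if more than 10% fail, an inference warning is
    attached to the results' metadata.  If every replicate fails, an
    :class:`InferenceError` is raised.
    """
    stratified = config.stratified
    if stratified is None:
        stratified = dataset.design.kind == "case_control"
    if stratified and (dataset.y.sum() == 0 or dataset.y.sum() == dataset.n):
        raise InferenceError("stratified resampling needs both cases and controls")

    def as_mapping(out) -> dict[str, float]:
        if isinstance(out, Mapping):
            return {str(k): float(v) for k, v in out.items()}
        return {"estimate": float(out)}

    point = as_mapping(pipeline(dataset))
    names = list(point)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_boot)
    replicates: dict[str, list[float]] = {k: [] for k in names}
    n_failed = 0
    for child in seeds:
        rng = np.random.default_rng(child)
        idx = _resample_indices(dataset, stratified, rng)
        try:
            rep = as_mapping(pipeline(dataset.subset(idx)))
        except PSPAFError as exc:
            n_failed += 1
            logger.debug("bootstrap replicate failed: %s", exc)
            continue
        for k in names:
            replicates[k].append(rep[k])

    n_ok = config.n_boot - n_failed
    if n_ok == 0:
        raise InferenceError("all bootstrap replicates failed")
    warn = n_failed > 0.10 * config.n_boot
    if warn:
        logger.warning("%d/%d bootstrap replicates failed to converge",
                       n_failed, config.n_boot)

    z = 1.96 if config.ci_level == 0.95 else float(norm.ppf((1 + config.ci_level) / 2))
    results: dict[str, PAFResult] = {}
    for k in names:
        reps = np.asarray(replicates[k])
        if len(reps) < 2 or np.ptp(reps) == 0.0:
            se = 0.0
        else:
            se = float(reps.std(ddof=1))
        if config.ci == "normal":
            lo, hi = point[k] - z * se, point[k] + z * se
        else:
            alpha = 1.0 - config.ci_level
            lo, hi = (float(np.quantile(reps, alpha / 2)),
                      float(np.quantile(reps, 1 - alpha / 2)))
        results[k] = PAFResult(
            estimand=k, estimate=point[k], se=se,
            ci_low=min(lo, hi), ci_high=max(lo, hi), n_boot=n_ok,
            metadata={"n_failed": n_failed, "seed": config.seed,
                      "stratified": stratified, "ci": config.ci,
                      **({"warning": "over 10% of replicates failed"} if warn else {})},
        )
    return results
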