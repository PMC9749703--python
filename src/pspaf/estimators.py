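"""Plug-in estimators for total, direct, indirect and pathway-specific PAFs.

Every estimator has the same plug-in form: a weighted average of fitted
outcome probabilities under a counterfactual substitution, compared against
the weighted case count,

    PAF-hat = [sum_i w_i Y_i  -  sum_i w_i q_i] / sum_i w_i Y_i ,

where ``q_i`` is the fitted probability of disease for record ``i`` after the
substitution that defines the estimand:

* pathway-specific (PS-PAF, mediator k): keep the observed exposure ``A_i``
  and replace ``M^k`` by its counterfactual-under-elimination representation
  — the mean-shifted value ``Mhat_i^k`` for continuous mediators, or an
  integral over the fitted level probabilities ``P(M^k = m | A=0, C_i)`` for
  discrete mediators;
* direct: set ``A = 0`` and keep all (or the one relevant) mediators at
  their observed values;
* total: set ``A = 0`` and give every mediator its counterfactual
  representation (g-formula standardization through the joint outcome model);
* indirect: total minus the single-mediator direct PAF (pure arithmetic);
* impact fraction: like the PS-PAF but with a caller-supplied
  post-intervention mediator distribution in place of the eliminated-exposure
  one.

Mediators must lie on separate causal pathways given exposure and covariates
(d-separated) for the joint-outcome-model estimators; mediators on the same
pathway (post-treatment confounding) are detected and rejected.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import StudyDataset
from .exceptions import (
    ContractError,
    DegenerateDataError,
    UnsupportedStructureError,
)
from .models import FittedMediatorModel, FittedOutcomeModel, shifted_mediator_values

__all__ = [
    "PAFResult",
    "CounterfactualDistribution",
    "counterfactual_distribution",
    "estimate_pspaf",
    "estimate_pspaf_continuous",
    "estimate_pspaf_discrete",
    "estimate_pspaf_joint",
    "estimate_direct_paf_all",
    "estimate_direct_paf_single",
    "estimate_total_paf",
    "estimate_indirect_paf",
    "estimate_impact_fraction",
    "results_to_frame",
    "results_to_json",
]


@dataclass
class PAFResult:
    """A point estimate for one estimand, optionally with bootstrap inference."""

    estimand: str
    estimate: float
    mediator: str | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ContractError("ci_low must not exceed ci_high")

    _LABELS = {"total": "paf_total", "direct_all": "paf_direct_all",
               "direct": "paf_direct", "indirect": "paf_indirect"}

    @property
    def label(self) -> str:
        """Canonical estimand label, e.g. ``paf_total`` or ``ps_paf[M]``."""
        stem = self._LABELS.get(self.estimand, self.estimand)
        return f"{stem}[{self.mediator}]" if self.mediator else stem


@dataclass
class CounterfactualDistribution:
    """Per-record representation of a (counterfactual) mediator distribution.

    Exactly one of ``values`` (continuous mediators: one substituted value per
    record) or ``probs`` (discrete mediators: per-record probability vector
    over ``levels``) is set.
    """

    mediator: str
    values: np.ndarray | None = None
    probs: np.ndarray | None = None
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if (self.values is None) == (self.probs is None):
            raise ContractError(
                "exactly one of values / probs must be supplied"
            )
        if self.probs is not None:
            if self.levels is None or self.probs.shape[1] != len(self.levels):
                raise ContractError("probs needs a matching levels tuple")
            if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-10):
                raise ContractError(
                    f"level probabilities for {self.mediator!r} do not sum to 1"
                )


def counterfactual_distribution(dataset: StudyDataset,
                                mediator_model: FittedMediatorModel,
                                a: float = 0.0) -> CounterfactualDistribution:
    """The fitted mediator distribution under exposure set to ``a``
    (``a=0`` gives the eliminated-exposure distribution used by PS-PAFs)."""
    spec = mediator_model.spec
    if spec.kind == "continuous":
        if a != 0.0:
            raise ContractError(
                "continuous counterfactual representation is only defined "
                "for exposure elimination (a=0)"
            )
        return CounterfactualDistribution(
            mediator=spec.name,
            values=shifted_mediator_values(dataset, mediator_model),
        )
    probs = mediator_model.predict_proba(dataset.df, a=a)
    return CounterfactualDistribution(mediator=spec.name, probs=probs,
                                      levels=tuple(spec.levels))


# ---------------------------------------------------------------------------
# the common plug-in machinery
# ---------------------------------------------------------------------------

def _weighted_case_sum(dataset: StudyDataset) -> float:
    swy = float(np.sum(dataset.weights * dataset.y))
    if swy == 0.0:
        raise DegenerateDataError("no weighted cases: sum_i w_i Y_i = 0")
    return swy


def _paf_from_qhat(dataset: StudyDataset, qhat: np.ndarray) -> float:
    swy = _weighted_case_sum(dataset)
    return (swy - float(np.sum(dataset.weights * qhat))) / swy


def _qhat_with_distribution(dataset: StudyDataset,
                            outcome_model: FittedOutcomeModel,
                            dist: CounterfactualDistribution,
                            extra_overrides: Mapping[str, object] | None = None
                            ) -> np.ndarray:
    """Fitted outcome probability with mediator ``dist.mediator`` substituted
    by ``dist``; exposure and everything else per ``extra_overrides`` (or
    observed)."""
    base = dict(extra_overrides or {})
    if dist.values is not None:
        base[dist.mediator] = dist.values
        return outcome_model.predict(dataset.df, base)
    qhat = np.zeros(dataset.n)
    for j, m in enumerate(dist.levels):
        ov = dict(base)
        ov[dist.mediator] = m
        qhat += dist.probs[:, j] * outcome_model.predict(dataset.df, ov)
    return qhat


def _require_d_separated(specs) -> None:
    bad = [s.name for s in specs if not s.d_separated]
    if bad:
        raise UnsupportedStructureError(
            f"mediator(s) {bad} are declared on a shared causal pathway "
            "(post-treatment confounding of the mediator-outcome "
            "relationship); joint-outcome-model estimation is only valid for "
            "d-separated mediators and alternative identification machinery "
            "for that setting is not implemented"
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_pspaf(dataset: StudyDataset,
                   outcome_model: FittedOutcomeModel,
                   mediator_model: FittedMediatorModel) -> PAFResult:
    """Pathway-specific PAF for one mediator (continuous or discrete).

    The outcome model may condition on just this mediator (single-mediator
    mode) or on all mediators (joint mode — the other mediators stay at their
    observed values automatically).  Records keep their observed exposure.
    """
    dist = counterfactual_distribution(dataset, mediator_model, a=0.0)
    qhat = _qhat_with_distribution(dataset, outcome_model, dist)
    return PAFResult(estimand="ps_paf", mediator=mediator_model.spec.name,
                     estimate=_paf_from_qhat(dataset, qhat))


def estimate_pspaf_continuous(dataset: StudyDataset,
                              outcome_model: FittedOutcomeModel,
                              mediator_model: FittedMediatorModel) -> PAFResult:
    if mediator_model.kind != "continuous":
        raise ContractError("estimate_pspaf_continuous needs a continuous mediator")
    return estimate_pspaf(dataset, outcome_model, mediator_model)


def estimate_pspaf_discrete(dataset: StudyDataset,
                            outcome_model: FittedOutcomeModel,
                            mediator_model: FittedMediatorModel) -> PAFResult:
    if mediator_model.kind != "discrete":
        raise ContractError("estimate_pspaf_discrete needs a discrete mediator")
    return estimate_pspaf(dataset, outcome_model, mediator_model)


def estimate_pspaf_joint(dataset: StudyDataset,
                         joint_outcome_model: FittedOutcomeModel,
                         mediator_model: FittedMediatorModel) -> PAFResult:
    """PS-PAF through a single joint outcome model conditioning on all
    mediators; requires every declared mediator to be d-separated."""
    _require_d_separated(dataset.mediator_specs)
    return estimate_pspaf(dataset, joint_outcome_model, mediator_model)


def estimate_direct_paf_all(dataset: StudyDataset,
                            joint_outcome_model: FittedOutcomeModel) -> PAFResult:
    """Direct PAF relative to all declared mediators: set A=0, keep every
    mediator at its observed value."""
    qhat = joint_outcome_model.predict(dataset.df, {dataset.exposure: 0.0})
    return PAFResult(estimand="direct_all",
                     estimate=_paf_from_qhat(dataset, qhat))


def estimate_direct_paf_single(dataset: StudyDataset,
                               outcome_model_k: FittedOutcomeModel,
                               k: str) -> PAFResult:
    """Single-mediator direct PAF (Sjolander's form): set A=0, keep mediator
    ``k`` at its observed value; ``outcome_model_k`` conditions on A, C, M^k."""
    dataset.spec(k)  # raises if k is not a declared mediator
    qhat = outcome_model_k.predict(dataset.df, {dataset.exposure: 0.0})
    return PAFResult(estimand="direct", mediator=k,
                     estimate=_paf_from_qhat(dataset, qhat))


def estimate_total_paf(dataset: StudyDataset,
                       joint_outcome_model: FittedOutcomeModel,
                       mediator_models: Sequence[FittedMediatorModel]) -> PAFResult:
    """Total PAF by g-formula standardization through the joint outcome model.

    Evaluates the outcome model at A=0 with every continuous mediator at its
    mean-shifted value and every discrete mediator integrated over its fitted
    level distribution given A=0 (mediators independent given A and C under
    d-separation).
    """
    _require_d_separated(dataset.mediator_specs)
    by_name = {m.spec.name: m for m in mediator_models}
    missing = [s.name for s in dataset.mediator_specs if s.name not in by_name]
    if missing:
        raise ContractError(f"no mediator model supplied for {missing}")

    base: dict[str, object] = {dataset.exposure: 0.0}
    discrete: list[tuple[str, tuple, np.ndarray]] = []
    for spec in dataset.mediator_specs:
        model = by_name[spec.name]
        if spec.kind == "continuous":
            base[spec.name] = shifted_mediator_values(dataset, model)
        else:
            probs = model.predict_proba(dataset.df, a=0.0)
            discrete.append((spec.name, tuple(spec.levels), probs))

    if not discrete:
        qhat = joint_outcome_model.predict(dataset.df, base)
    else:
        qhat = np.zeros(dataset.n)
        level_sets = [levels for _, levels, _ in discrete]
        for combo in itertools.product(*[range(len(ls)) for ls in level_sets]):
            ov = dict(base)
            wgt = np.ones(dataset.n)
            for (name, levels, probs), j in zip(discrete, combo):
                ov[name] = levels[j]
                wgt = wgt * probs[:, j]
            qhat += wgt * joint_outcome_model.predict(dataset.df, ov)
    return PAFResult(estimand="total", estimate=_paf_from_qhat(dataset, qhat))


def estimate_indirect_paf(total: PAFResult, direct_single_k: PAFResult) -> PAFResult:
    """Indirect PAF for mediator k: total minus the single-mediator direct
    PAF.  Pure arithmetic — no refitting — so additivity holds exactly."""
    if total.estimand != "total" or direct_single_k.estimand != "direct":
        raise ContractError(
            "estimate_indirect_paf expects a total-PAF result and a "
            "single-mediator direct-PAF result"
        )
    return PAFResult(estimand="indirect", mediator=direct_single_k.mediator,
                     estimate=total.estimate - direct_single_k.estimate)


def estimate_impact_fraction(dataset: StudyDataset,
                             outcome_model: FittedOutcomeModel,
                             intervention_distribution: CounterfactualDistribution,
                             k: str | None = None) -> PAFResult:
    """Pathway-specific impact fraction for a partial intervention.

    Identical plug-in form to the PS-PAF, with the caller-supplied
    post-intervention mediator distribution replacing the
    eliminated-exposure distribution.  Supplying the fitted A=0 distribution
    recovers the PS-PAF; supplying the observed mediator values gives zero.
    """
    if k is not None and intervention_distribution.mediator != k:
        raise ContractError(
            f"distribution is for mediator {intervention_distribution.mediator!r}, "
            f"not {k!r}"
        )
    if intervention_distribution.values is not None and (
            len(intervention_distribution.values) != dataset.n):
        raise ContractError("distribution values length does not match dataset")
    if intervention_distribution.probs is not None and (
            intervention_distribution.probs.shape[0] != dataset.n):
        raise ContractError("distribution probs length does not match dataset")
    qhat = _qhat_with_distribution(dataset, outcome_model,
                                   intervention_distribution)
    return PAFResult(estimand="impact_fraction",
                     mediator=intervention_distribution.mediator,
                     estimate=_paf_from_qhat(dataset, qhat))


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[PAFResult]) -> pd.DataFrame:
    """One row per estimand, mirroring the usual results-table layout."""
    rows = []
    for r in results:
        rows.append({
            "estimand": r.label,
            "mediator": r.mediator or "",
            "estimate": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "n_boot": r.n_boot,
        })
    return pd.DataFrame(rows)


def results_to_json(results: Sequence[PAFResult], **metadata) -> str:
    payload = {"metadata": metadata, "results": []}
    for r in results:
        payload["results"].append({
            "estimand": r.estimand, "mediator": r.mediator,
            "estimate": r.estimate, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "n_boot": r.n_boot,
            **({"metadata": r.metadata} if r.metadata else {}),
        })
    return json.dumps(payload, indent=2)
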