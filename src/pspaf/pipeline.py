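"""End-to-end estimation plans: fit all nuisance models, compute every PAF.

An :class:`AnalysisPlan` records which terms enter the joint outcome model
and each mediator model.  :func:`estimate_all` executes the plan — fitting
the joint outcome model, one reduced outcome model per mediator (for the
single-mediator direct PAFs) and one model per mediator — and returns every
estimand.  :func:`make_pipeline` wraps the same computation as a
refit-from-scratch callable for the bootstrap.

Estimand labels match :class:`pspaf.sem.OracleFunctionals.as_dict` so that
estimates can be compared against oracle values key by key: ``paf_total``,
``paf_direct_all``, and per mediator ``ps_paf[k]``, ``paf_direct[k]``,
``paf_indirect[k]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .data import StudyDataset
from .estimators import (
    PAFResult,
    estimate_direct_paf_all,
    estimate_direct_paf_single,
    estimate_indirect_paf,
    estimate_pspaf_joint,
    estimate_total_paf,
)
from .exceptions import ConfigurationError
from .formulas import ModelFormula, Term
from .models import fit_mediator_model, fit_outcome_model

__all__ = ["AnalysisPlan", "estimate_all", "make_pipeline", "saturated_terms"]

_ALL_ESTIMANDS = ("total", "direct_all", "ps_paf", "direct", "indirect")


def saturated_terms(columns: Sequence[str]) -> tuple[Term, ...]:
    """Main effects plus every interaction product of the given columns
    (a saturated design when all columns are binary)."""
    terms = []
    for r in range(1, len(columns) + 1):
        for combo in itertools.combinations(columns, r):
            terms.append(Term(":".join(combo)))
    return tuple(terms)


@dataclass(frozen=True)
class AnalysisPlan:
    """What to fit and what to estimate.

    ``outcome_terms`` define the joint outcome model (exposure, covariate and
    mediator terms).  ``mediator_terms`` gives the covariate terms of each
    mediator model (the exposure main effect is always included).  Reduced
    single-mediator outcome models are derived by dropping every term that
    references another mediator, unless overridden via
    ``single_outcome_terms``.
    """

    outcome_terms: tuple[Term, ...]
    mediator_terms: Mapping[str, tuple[Term, ...]] = field(default_factory=dict)
    single_outcome_terms: Mapping[str, tuple[Term, ...]] | None = None
    estimands: tuple[str, ...] = _ALL_ESTIMANDS
    use_weights: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.estimands) - set(_ALL_ESTIMANDS)
        if unknown:
            raise ConfigurationError(f"unknown estimand(s): {sorted(unknown)}")
        if not self.estimands:
            raise ConfigurationError("estimand list must be non-empty")

    def terms_for_single(self, dataset: StudyDataset, k: str) -> tuple[Term, ...]:
        if self.single_outcome_terms and k in self.single_outcome_terms:
            return tuple(self.single_outcome_terms[k])
        others = set(dataset.mediators) - {k}
        return tuple(t for t in self.outcome_terms
                     if not (set(t.name.split(":")) & others))


def estimate_all(dataset: StudyDataset, plan: AnalysisPlan) -> dict[str, PAFResult]:
    """Fit every model in the plan and compute the requested estimands."""
    for t in plan.outcome_terms:
        for col in t.name.split(":"):
            if col not in dataset.df.columns:
                raise ConfigurationError(f"outcome term column {col!r} not in data")
    for k in plan.mediator_terms:
        dataset.spec(k)  # raises for undeclared mediators

    joint = fit_outcome_model(
        dataset, ModelFormula(dataset.outcome, plan.outcome_terms),
        use_weights=plan.use_weights)
    med_models = {
        k: fit_mediator_model(dataset, dataset.spec(k),
                              plan.mediator_terms.get(k, ()),
                              use_weights=plan.use_weights)
        for k in dataset.mediators
    }

    need_single = {"direct", "indirect"} & set(plan.estimands)
    singles = {}
    if need_single:
        for k in dataset.mediators:
            terms = plan.terms_for_single(dataset, k)
            if set(terms) == set(plan.outcome_terms):
                singles[k] = joint  # one mediator: the joint model already is it
            else:
                singles[k] = fit_outcome_model(
                    dataset, ModelFormula(dataset.outcome, terms),
                    use_weights=plan.use_weights)

    out: dict[str, PAFResult] = {}
    total = None
    if {"total", "indirect"} & set(plan.estimands):
        total = estimate_total_paf(dataset, joint, list(med_models.values()))
    if "total" in plan.estimands:
        out["paf_total"] = total
    if "direct_all" in plan.estimands:
        out["paf_direct_all"] = estimate_direct_paf_all(dataset, joint)
    for k in dataset.mediators:
        if "ps_paf" in plan.estimands:
            out[f"ps_paf[{k}]"] = estimate_pspaf_joint(dataset, joint, med_models[k])
        if need_single:
            direct_k = estimate_direct_paf_single(dataset, singles[k], k)
            if "direct" in plan.estimands:
                out[f"paf_direct[{k}]"] = direct_k
            if "indirect" in plan.estimands:
                out[f"paf_indirect[{k}]"] = estimate_indirect_paf(total, direct_k)
    return out


def make_pipeline(plan: AnalysisPlan) -> Callable[[StudyDataset], dict[str, float]]:
    """A refit-and-estimate callable for :func:`pspaf.bootstrap.bootstrap_estimate`."""

    def pipeline(ds: StudyDataset) -> dict[str, float]:
        return {k: r.estimate for k, r in estimate_all(ds, plan).items()}

    return pipeline
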