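"""PAF estimators: reductions, identities, invariances and consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pspaf import (
    AnalysisPlan,
    CounterfactualDistribution,
    MediatorSpec,
    ModelFormula,
    StudyDataset,
    StudyDesign,
    Term,
    counterfactual_distribution,
    estimate_all,
    estimate_direct_paf_all,
    estimate_direct_paf_single,
    estimate_impact_fraction,
    estimate_indirect_paf,
    estimate_pspaf,
    estimate_pspaf_continuous,
    estimate_pspaf_discrete,
    estimate_pspaf_joint,
    estimate_total_paf,
    fit_mediator_model,
    fit_outcome_model,
    mc_oracle,
    saturated_terms,
    simulate_cohort,
)
from pspaf.exceptions import (
    ContractError,
    DegenerateDataError,
    UnsupportedStructureError,
)
from pspaf.sem import GaussianNode, StructuralModel, bernoulli_node

from conftest import BASE_SEED, replication_se

SAT = saturated_terms(["A", "M"])


def _fit_toy(ds, link="logit"):
    om = fit_outcome_model(ds, ModelFormula("Y", SAT), link=link)
    mm = fit_mediator_model(ds, ds.spec("M"))
    return om, mm


def _as_continuous(ds):
    """The same records with the binary mediator redeclared as continuous."""
    return StudyDataset(df=ds.df, outcome=ds.outcome, exposure=ds.exposure,
                        covariates=ds.covariates,
                        mediator_specs=(MediatorSpec("M", "continuous"),),
                        design=ds.design)


class TestNullAndReductionCases:
    def test_zero_exposure_effect_mediator_gives_zero_pspaf(self, small_cohort):
        ds = _as_continuous(small_cohort)
        om, mm = _fit_toy(ds)
        mm.coefficients[1] = 0.0  # no fitted exposure effect on the mediator
        res = estimate_pspaf_continuous(ds, om, mm)
        assert abs(res.estimate) < 1e-6

    def test_mediator_independent_of_exposure_gives_zero_pspaf(self, balanced_dataset):
        # empirical M distribution identical across exposure strata and
        # saturated models: counterfactual distribution equals observed
        ds = balanced_dataset
        om, mm = _fit_toy(ds)
        res = estimate_pspaf_discrete(ds, om, mm)
        assert abs(res.estimate) < 1e-6

    def test_exposure_null_outcome_model_gives_zero_direct_paf(self, small_cohort):
        # a fitted exposure coefficient of exactly zero (here: exposure not in
        # the model) makes the A=0 substitution a no-op, and the intercept
        # score equation then forces the numerator to zero
        ds = small_cohort
        om = fit_outcome_model(ds, ModelFormula("Y", [Term("M")]))
        assert abs(estimate_direct_paf_all(ds, om).estimate) < 1e-6

    def test_single_mediator_joint_equals_single(self, small_cohort):
        ds = small_cohort
        om, mm = _fit_toy(ds)
        joint = estimate_pspaf_joint(ds, om, mm)
        single = estimate_pspaf(ds, om, mm)
        assert joint.estimate == pytest.approx(single.estimate, abs=1e-12)
        d_all = estimate_direct_paf_all(ds, om)
        d_k = estimate_direct_paf_single(ds, om, "M")
        assert d_all.estimate == pytest.approx(d_k.estimate, abs=1e-12)

    def test_degenerate_counterfactual_distribution(self, small_cohort):
        ds = small_cohort
        om, _ = _fit_toy(ds)
        n = ds.n
        # all mass on level 1: every record is plugged with M=1
        dist = CounterfactualDistribution(
            mediator="M", probs=np.column_stack([np.zeros(n), np.ones(n)]),
            levels=(0, 1))
        res = estimate_impact_fraction(ds, om, dist)
        qhat = om.predict(ds.df, {"M": 1})
        swy = float(np.sum(ds.weights * ds.y))
        assert res.estimate == pytest.approx(
            (swy - float(np.sum(ds.weights * qhat))) / swy, abs=1e-12)


class TestImpactFraction:
    def test_a0_distribution_reduces_to_pspaf(self, small_cohort):
        ds = small_cohort
        om, mm = _fit_toy(ds)
        dist = counterfactual_distribution(ds, mm, a=0.0)
        ps = estimate_pspaf(ds, om, mm)
        imp = estimate_impact_fraction(ds, om, dist, "M")
        assert imp.estimate == pytest.approx(ps.estimate, abs=1e-12)

    def test_observed_distribution_gives_zero(self, small_cohort):
        ds = small_cohort
        om, _ = _fit_toy(ds)
        m = ds.df["M"].to_numpy(float)
        obs = CounterfactualDistribution(
            mediator="M", probs=np.column_stack([1 - m, m]), levels=(0, 1))
        assert abs(estimate_impact_fraction(ds, om, obs).estimate) < 1e-6

    def test_attenuated_shift_lies_between_zero_and_pspaf(self, small_cohort):
        ds = _as_continuous(small_cohort)
        om, mm = _fit_toy(ds)
        full = counterfactual_distribution(ds, mm, a=0.0)
        ps = estimate_pspaf_continuous(ds, om, mm).estimate
        m = ds.df["M"].to_numpy(float)
        half = CounterfactualDistribution(
            mediator="M", values=m - 0.5 * (m - full.values))
        imp = estimate_impact_fraction(ds, om, half, "M").estimate
        assert 0.0 <= imp <= ps

    def test_malformed_distribution_rejected(self, small_cohort):
        with pytest.raises(ContractError):
            CounterfactualDistribution(mediator="M")
        with pytest.raises(ContractError):
            CounterfactualDistribution(
                mediator="M", probs=np.array([[0.5, 0.4]]), levels=(0, 1))
        ds = small_cohort
        om, _ = _fit_toy(ds)
        with pytest.raises(ContractError, match="length"):
            estimate_impact_fraction(
                ds, om, CounterfactualDistribution(mediator="M",
                                                   values=np.zeros(3)), "M")


class TestInvariances:
    def test_estimates_invariant_to_record_order(self, small_cohort, toy1_plan):
        ds = small_cohort
        base = {k: r.estimate for k, r in estimate_all(ds, toy1_plan).items()}
        perm = np.random.default_rng(2).permutation(ds.n)
        shuffled = ds.subset(perm)
        out = {k: r.estimate for k, r in estimate_all(shuffled, toy1_plan).items()}
        for k in base:
            assert out[k] == pytest.approx(base[k], abs=1e-10)

    def test_estimates_invariant_to_record_duplication(self, small_cohort, toy1_plan):
        ds = small_cohort
        base = {k: r.estimate for k, r in estimate_all(ds, toy1_plan).items()}
        doubled = ds.subset(np.tile(np.arange(ds.n), 2))
        out = {k: r.estimate for k, r in estimate_all(doubled, toy1_plan).items()}
        for k in base:
            assert out[k] == pytest.approx(base[k], abs=1e-8)

    def test_estimates_bounded_above_by_one(self, small_cohort, toy1_plan):
        for r in estimate_all(small_cohort, toy1_plan).values():
            assert r.estimate <= 1.0


class TestStructureGuards:
    def test_shared_pathway_mediators_rejected(self, small_cohort):
        ds = small_cohort
        bad = StudyDataset(
            df=ds.df, outcome="Y", exposure="A", covariates=(),
            mediator_specs=(MediatorSpec("M", "discrete", (0, 1),
                                         d_separated=False),),
            design=ds.design)
        om, mm = _fit_toy(bad)
        with pytest.raises(UnsupportedStructureError, match="pathway"):
            estimate_pspaf_joint(bad, om, mm)
        with pytest.raises(UnsupportedStructureError):
            estimate_total_paf(bad, om, [mm])

    def test_no_weighted_cases_rejected(self, small_cohort):
        ds = small_cohort
        om, mm = _fit_toy(ds)
        no_cases = StudyDataset(
            df=ds.df.assign(Y=0), outcome="Y", exposure="A", covariates=(),
            mediator_specs=ds.mediator_specs, design=ds.design)
        with pytest.raises(DegenerateDataError):
            estimate_pspaf(no_cases, om, mm)

    def test_wrong_kind_dispatch_rejected(self, small_cohort):
        ds = small_cohort
        om, mm = _fit_toy(ds)
        with pytest.raises(ContractError):
            estimate_pspaf_continuous(ds, om, mm)  # mediator is discrete

    def test_indirect_requires_matching_results(self, small_cohort, toy1_plan):
        out = estimate_all(small_cohort, toy1_plan)
        with pytest.raises(ContractError):
            estimate_indirect_paf(out["paf_direct[M]"], out["paf_total"])


def test_mean_shift_estimator_matches_oracle_under_linear_risk(
        toy1_cohort_200k, toy1_oracle):
    """For a binary mediator the mean-shift (continuous) estimator is
    consistent when the outcome model is linear in the mediator on the
    probability scale — exactly the structure of the canonical SEM — and
    then agrees with the level-sum (discrete) estimator."""
    ds = _as_continuous(toy1_cohort_200k)
    om = fit_outcome_model(ds, ModelFormula("Y", SAT), link="identity")
    mm = fit_mediator_model(ds, ds.spec("M"))
    res = estimate_pspaf_continuous(ds, om, mm)
    assert res.estimate == pytest.approx(toy1_oracle.ps_paf("M"), abs=0.012)


def _gaussian_mediator_model():
    c = GaussianNode("C", (), lambda v, n: np.zeros(n), sd=1.0)
    a = bernoulli_node("A", ("C",), lambda v: expit(-0.2 + 0.4 * v["C"]))
    m = GaussianNode("M", ("A", "C"),
                     lambda v, n: 1.0 + 1.5 * v["A"] + 0.5 * v["C"], sd=1.0)
    y = bernoulli_node("Y", ("A", "M", "C"),
                       lambda v: expit(-2.0 + 0.5 * v["A"] + 0.6 * v["M"]
                                       + 0.3 * v["C"]))
    return StructuralModel(nodes=(c, a, m, y), covariates=("C",),
                           exposure="A", mediators=("M",), outcome="Y")


def test_continuous_mediator_estimators_consistent_for_gaussian_sem():
    """With a correctly specified logistic outcome model and linear mediator
    model, every estimand converges to its Monte-Carlo oracle value."""
    model = _gaussian_mediator_model()
    oracle = mc_oracle(model, n_draws=400_000, seed=BASE_SEED + 10)
    ds = simulate_cohort(model, 100_000, seed=BASE_SEED + 11)
    plan = AnalysisPlan(
        outcome_terms=(Term("A"), Term("M"), Term("C")),
        mediator_terms={"M": (Term("C"),)},
    )
    est = {k: r.estimate for k, r in estimate_all(ds, plan).items()}
    truth = oracle.as_dict()
    mc_se = replication_se(model, plan, n_small=20_000, reps=12,
                           n_target=100_000, seed=BASE_SEED + 12)
    for key in ("paf_total", "paf_direct_all", "ps_paf[M]",
                "paf_direct[M]", "paf_indirect[M]"):
        tol = 3 * np.hypot(mc_se[key], oracle.se[key])
        assert est[key] == pytest.approx(truth[key], abs=tol), key
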