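"""Outcome and mediator model fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pspaf import (
    MediatorSpec,
    ModelFormula,
    StudyDataset,
    StudyDesign,
    Term,
    fit_mediator_model,
    fit_outcome_model,
    shifted_mediator_values,
    simulate_cohort,
    toy1,
)
from pspaf.exceptions import ContractError, EstimationError

from conftest import BASE_SEED


def _dataset(df, specs=(MediatorSpec("M", "continuous"),), design=None):
    return StudyDataset(df=df, outcome="Y", exposure="A", covariates=(),
                        mediator_specs=tuple(specs),
                        design=design or StudyDesign("cohort"))


def test_saturated_logit_recovers_empirical_proportions():
    # 2x2 cohort: P(Y|A=0)=0.10, P(Y|A=1)=0.30
    df = pd.DataFrame({
        "A": np.repeat([0, 1], 100),
        "Y": np.concatenate([np.repeat([1, 0], [10, 90]),
                             np.repeat([1, 0], [30, 70])]),
    }).assign(M=0.0)
    ds = _dataset(df)
    om = fit_outcome_model(ds, ModelFormula("Y", [Term("A")]))
    p = om.predict(ds.df, overrides={"A": 0.0})
    assert p[0] == pytest.approx(0.10, abs=1e-8)
    p1 = om.predict(ds.df, overrides={"A": 1.0})
    assert p1[0] == pytest.approx(0.30, abs=1e-8)


def test_intercept_score_equation_holds_with_weights(toy1_model):
    from pspaf.sem import sample_case_control
    ds = sample_case_control(toy1_model, n_cases=400, r=2, seed=BASE_SEED + 2)
    om = fit_outcome_model(ds, ModelFormula("Y", [Term("A"), Term("M"),
                                                  Term("A:M")]))
    p = om.predict(ds.df)
    assert abs(np.sum(ds.weights * (ds.y - p))) / np.sum(ds.weights) < 1e-6


def test_logistic_coefficient_recovery_from_known_model():
    rng = np.random.default_rng(BASE_SEED + 3)
    n = 50_000
    truth = np.array([-1.0, 0.8, 0.5])
    x = rng.normal(size=n)
    a = rng.binomial(1, 0.5, n)
    y = rng.binomial(1, expit(truth[0] + truth[1] * a + truth[2] * x))
    ds = _dataset(pd.DataFrame({"Y": y, "A": a, "M": x}))
    om = fit_outcome_model(ds, ModelFormula("Y", [Term("A"), Term("M")]))
    bse = om.diagnostics["bse"]
    assert np.all(np.abs(om.coefficients - truth) < 3 * bse)


def test_perfect_separation_raises():
    df = pd.DataFrame({"A": [0, 0, 1, 1] * 5, "Y": [0, 0, 1, 1] * 5,
                       "M": 0.0})
    with pytest.raises(EstimationError, match="separation"):
        fit_outcome_model(_dataset(df), ModelFormula("Y", [Term("A")]))


def test_rank_deficient_outcome_design_raises(small_cohort):
    ds = small_cohort
    ds.df["A2"] = ds.df["A"]
    with pytest.raises(EstimationError, match="rank deficient"):
        fit_outcome_model(ds, ModelFormula("Y", [Term("A"), Term("A2")]))


def test_continuous_mediator_exposure_effect_recovery():
    rng = np.random.default_rng(BASE_SEED + 4)
    n = 10_000
    a = rng.binomial(1, 0.5, n)
    m = 1.0 + 2.0 * a + rng.normal(size=n)
    y = rng.binomial(1, 0.2, n)
    y[0] = 1  # ensure at least one case regardless of draw
    ds = _dataset(pd.DataFrame({"Y": y, "A": a, "M": m}))
    mm = fit_mediator_model(ds, ds.spec("M"))
    assert abs(mm.coefficients[1] - 2.0) < 3 * mm.diagnostics["bse"][1]


def test_binary_mediator_null_exposure_effect():
    rng = np.random.default_rng(BASE_SEED + 5)
    n = 20_000
    a = rng.binomial(1, 0.5, n)
    m = rng.binomial(1, 0.4, n)  # independent of A
    y = rng.binomial(1, 0.1, n)
    y[0] = 1
    ds = _dataset(pd.DataFrame({"Y": y, "A": a, "M": m}),
                  specs=(MediatorSpec("M", "discrete", (0, 1)),))
    mm = fit_mediator_model(ds, ds.spec("M"))
    p0 = mm.predict_proba(ds.df, a=0.0)[0, 1]
    p1 = mm.predict_proba(ds.df, a=1.0)[0, 1]
    assert abs(mm.coefficients[1]) < 3 * mm.diagnostics["bse"][1]
    assert abs(p0 - p1) < 0.05


def test_three_level_mediator_probabilities_normalize():
    rng = np.random.default_rng(BASE_SEED + 6)
    n = 3_000
    a = rng.binomial(1, 0.5, n)
    probs = np.column_stack([0.5 - 0.2 * a, 0.3 + 0.1 * a, 0.2 + 0.1 * a])
    m = np.array([rng.choice(3, p=p) for p in probs])
    y = rng.binomial(1, 0.2, n)
    y[0] = 1
    ds = _dataset(pd.DataFrame({"Y": y, "A": a, "M": m}),
                  specs=(MediatorSpec("M", "discrete", (0, 1, 2)),))
    mm = fit_mediator_model(ds, ds.spec("M"))
    for aval in (0.0, 1.0, None):
        pr = mm.predict_proba(ds.df, a=aval)
        assert np.all(np.abs(pr.sum(axis=1) - 1.0) < 1e-10)
        assert np.all(pr >= 0)


def test_absent_declared_level_raises():
    df = pd.DataFrame({"Y": [1, 0, 0, 1], "A": [0, 1, 0, 1], "M": [0, 0, 1, 1]})
    ds = _dataset(df, specs=(MediatorSpec("M", "discrete", (0, 1, 2)),))
    with pytest.raises(EstimationError, match=r"\[2\]"):
        fit_mediator_model(ds, ds.spec("M"))


class TestShiftedMediatorValues:
    def test_unexposed_records_unchanged(self, small_cohort):
        ds = small_cohort
        spec = MediatorSpec("M", "continuous")
        ds2 = StudyDataset(df=ds.df, outcome="Y", exposure="A", covariates=(),
                           mediator_specs=(spec,), design=ds.design)
        mm = fit_mediator_model(ds2, spec)
        mhat = shifted_mediator_values(ds2, mm)
        a = ds2.a
        m = ds2.df["M"].to_numpy(float)
        assert np.array_equal(mhat[a == 0], m[a == 0])
        # exposed records: shift equals the fitted exposure coefficient
        shift = mm.coefficients[1]
        assert np.allclose(mhat[a == 1], m[a == 1] - shift)

    def test_zero_exposure_effect_leaves_values_unchanged(self, small_cohort):
        ds = small_cohort
        spec = MediatorSpec("M", "continuous")
        ds2 = StudyDataset(df=ds.df, outcome="Y", exposure="A", covariates=(),
                           mediator_specs=(spec,), design=ds.design)
        mm = fit_mediator_model(ds2, spec)
        mm.coefficients[1] = 0.0
        assert np.array_equal(shifted_mediator_values(ds2, mm),
                              ds2.df["M"].to_numpy(float))

    def test_discrete_model_rejected(self, small_cohort):
        mm = fit_mediator_model(small_cohort, small_cohort.spec("M"))
        assert mm.kind == "discrete"
        with pytest.raises(ContractError):
            shifted_mediator_values(small_cohort, mm)
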