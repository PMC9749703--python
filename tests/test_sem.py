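"""Structural-equation simulator: oracles, sampling, serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pspaf import (
    compute_weights,
    enumerate_oracle,
    make_interstroke_like,
    mc_oracle,
    sample_case_control,
    simulate_cohort,
    two_mediator_toy,
    verify_identification_equivalence,
)
from pspaf.exceptions import (
    ConfigurationError,
    ContractError,
    DegenerateDataError,
    ResourceError,
    UnsupportedStructureError,
)
from pspaf.sem import (
    DiscreteNode,
    StructuralModel,
    bernoulli_node,
    model_from_dict,
    model_to_dict,
)

from conftest import BASE_SEED


class TestEnumerationOracle:
    def test_toy1_exact_functionals(self, toy1_oracle):
        o = toy1_oracle
        assert o.p_y == pytest.approx(0.45, abs=1e-12)
        assert o.p_y0 == pytest.approx(0.18, abs=1e-12)
        assert o.paf_total == pytest.approx(0.6, abs=1e-12)
        assert o.ps_paf("M") == pytest.approx(4 / 15, abs=1e-12)
        assert o.paf_direct("M") == pytest.approx(1 / 3, abs=1e-12)
        assert o.paf_indirect("M") == pytest.approx(4 / 15, abs=1e-12)
        assert o.p_interventional["M"] == pytest.approx(0.33, abs=1e-12)
        assert o.p_mechanistic["M"] == pytest.approx(0.33, abs=1e-12)

    def test_blocked_pathway_gives_zero_pspaf(self):
        a = bernoulli_node("A", (), lambda v: 0.5)
        m = bernoulli_node("M", ("A",), lambda v: 0.2 + 0.6 * v["A"])
        y = bernoulli_node("Y", ("A",), lambda v: 0.1 + 0.3 * v["A"])  # no M->Y
        model = StructuralModel(nodes=(a, m, y), covariates=(), exposure="A",
                                mediators=("M",), outcome="Y")
        o = enumerate_oracle(model)
        assert o.ps_paf("M") == pytest.approx(0.0, abs=1e-14)

    def test_continuous_node_unsupported(self):
        _, model = make_interstroke_like(seed=0, n=100)
        with pytest.raises(UnsupportedStructureError):
            enumerate_oracle(model)

    def test_support_size_guard(self, toy1_model):
        with pytest.raises(ResourceError):
            enumerate_oracle(toy1_model, max_worlds=2)

    def test_matches_monte_carlo(self, toy1_model, toy1_oracle):
        mc = mc_oracle(toy1_model, n_draws=300_000, seed=BASE_SEED + 20)
        for key, truth in toy1_oracle.as_dict().items():
            if isinstance(truth, str):
                continue
            se = max(mc.se.get(key, 0.002), 1e-4)
            assert mc.as_dict()[key] == pytest.approx(truth, abs=4 * se), key


class TestIdentificationEquivalence:
    def test_d_separated_models_equivalent(self, toy1_model):
        for model in (toy1_model, two_mediator_toy()):
            report = verify_identification_equivalence(model)
            assert report["equivalent"]
            for gaps in report["gaps"].values():
                assert gaps["mechanistic"] <= 1e-12
                assert gaps["identification"] <= 1e-12

    def test_sequential_structure_reports_gap_without_raising(self):
        # M1 -> M2: post-treatment confounding; mechanistic and
        # interventional functionals genuinely differ for M2
        a = bernoulli_node("A", (), lambda v: 0.5)
        m1 = bernoulli_node("M1", ("A",), lambda v: expit(-1 + 2 * v["A"]))
        m2 = bernoulli_node("M2", ("A", "M1"),
                            lambda v: expit(-1 + 0.5 * v["A"] + 2 * v["M1"]))
        y = bernoulli_node("Y", ("A", "M1", "M2"),
                           lambda v: expit(-2 + 0.5 * v["A"] + v["M1"]
                                           + 1.5 * v["M2"]))
        model = StructuralModel(nodes=(a, m1, m2, y), covariates=(),
                                exposure="A", mediators=("M1", "M2"),
                                outcome="Y", mediator_structure="sequential")
        report = verify_identification_equivalence(model)
        assert not report["equivalent"]
        assert report["gaps"]["M2"]["identification"] > 1e-6


class TestCohortSimulation:
    def test_empty_cohort_rejected(self, toy1_model):
        with pytest.raises(DegenerateDataError):
            simulate_cohort(toy1_model, 0)

    def test_disease_prevalence_matches_oracle(self, toy1_cohort_200k, toy1_oracle):
        n = toy1_cohort_200k.n
        bound = 3 * np.sqrt(0.45 * 0.55 / n)
        assert abs(toy1_cohort_200k.y.mean() - toy1_oracle.p_y) < bound

    def test_seed_reproducibility(self, toy1_model):
        d1 = simulate_cohort(toy1_model, 500, seed=42).df
        d2 = simulate_cohort(toy1_model, 500, seed=42).df
        d3 = simulate_cohort(toy1_model, 500, seed=43).df
        pd.testing.assert_frame_equal(d1, d2)
        assert not d1.equals(d3)


class TestCaseControlSampling:
    def test_counts_and_design(self, toy1_model):
        ds = sample_case_control(toy1_model, n_cases=1000, r=1,
                                 seed=BASE_SEED + 21)
        assert int(ds.y.sum()) == 1000
        assert ds.n == 2000
        assert ds.design.kind == "case_control"
        assert ds.design.prevalence == pytest.approx(0.45, abs=1e-12)
        # control weight for pi = 0.45, r = 1
        assert ds.weights.max() == pytest.approx((1 / 0.45 - 1), abs=1e-10)

    def test_reweighting_recovers_population_exposure(self, toy1_model,
                                                      toy1_cohort_200k):
        ds = sample_case_control(toy1_model, n_cases=2000, r=1,
                                 seed=BASE_SEED + 22)
        w_prev = float(np.sum(ds.weights * ds.a) / ds.weights.sum())
        se = 0.5 / np.sqrt(ds.n)  # binomial bound on the weighted mean
        assert abs(w_prev - 0.5) < 4 * se

    def test_bad_arguments(self, toy1_model):
        with pytest.raises(ConfigurationError):
            sample_case_control(toy1_model, n_cases=0)
        with pytest.raises(ConfigurationError):
            sample_case_control(toy1_model, n_cases=10, r=0.5)


class TestStrokeStudyGenerator:
    def test_incidence_calibration(self):
        ds, model = make_interstroke_like(seed=BASE_SEED + 23, n=1_000_000)
        inc = ds.y.mean()
        assert abs(inc - 0.0035) / 0.0035 < 0.10
        assert model.true_prevalence == pytest.approx(0.0035)

    def test_global_null_exposure(self):
        _, model = make_interstroke_like(seed=0, n=100, exposure_effect=0.0)
        o = mc_oracle(model, n_draws=200_000, seed=BASE_SEED + 24)
        for k, v in o.as_dict().items():
            if isinstance(v, str) or k in ("p_y", "p_y0"):
                continue
            se = max(o.se.get(k, 0.002), 5e-4)
            assert abs(v) < 4 * se, (k, v)

    def test_reproducible_dataset_hash(self):
        d1, _ = make_interstroke_like(seed=9, n_cases=200, r=1)
        d2, _ = make_interstroke_like(seed=9, n_cases=200, r=1)
        h1 = pd.util.hash_pandas_object(d1.df).sum()
        h2 = pd.util.hash_pandas_object(d2.df).sum()
        assert h1 == h2

    def test_case_control_mode_weights(self):
        ds, _ = make_interstroke_like(seed=10, n_cases=200, r=1)
        assert int(ds.y.sum()) == 200
        assert int(ds.weights.max()) == 284


class TestSerialization:
    def test_discrete_model_round_trip(self, toy1_model, toy1_oracle):
        rebuilt = model_from_dict(model_to_dict(toy1_model))
        o = enumerate_oracle(rebuilt)
        for key, truth in toy1_oracle.as_dict().items():
            if isinstance(truth, str):
                continue
            assert o.as_dict()[key] == pytest.approx(truth, abs=1e-12), key

    def test_continuous_model_not_serializable(self):
        _, model = make_interstroke_like(seed=0, n=50)
        with pytest.raises(UnsupportedStructureError):
            model_to_dict(model)

    def test_bad_cpt_rejected(self):
        from pspaf.sem import tabular_node
        with pytest.raises(ConfigurationError):
            tabular_node("X", (0, 1), (), (), {(): [0.5, 0.4]})


def test_model_role_validation():
    a = bernoulli_node("A", (), lambda v: 0.5)
    y = bernoulli_node("Y", ("A",), lambda v: 0.2 + 0.3 * v["A"])
    with pytest.raises(ConfigurationError, match="unknown node"):
        StructuralModel(nodes=(a, y), covariates=(), exposure="A",
                        mediators=("M",), outcome="Y")
    m_bad = DiscreteNode("M", (0, 1, 2), ("Z",), lambda v, n: None)
    with pytest.raises(ConfigurationError, match="precede"):
        StructuralModel(nodes=(a, m_bad, y), covariates=(), exposure="A",
                        mediators=("M",), outcome="Y")
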