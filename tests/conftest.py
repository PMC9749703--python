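import numpy as np
import pandas as pd
import pytest

from pspaf import (
    AnalysisPlan,
    MediatorSpec,
    StudyDataset,
    StudyDesign,
    enumerate_oracle,
    saturated_terms,
    simulate_cohort,
    toy1,
)

from pspaf.pipeline import estimate_all as _estimate_all

# one fixed base seed for every stochastic fixture/test in the suite
BASE_SEED = 20260919


def replication_se(model, plan, n_small: int, reps: int, n_target: int,
                   seed: int) -> dict[str, float]:
    """Monte-Carlo SE of each estimand at sample size ``n_target``.

    Runs the full estimation pipeline on ``reps`` independent cohorts of size
    ``n_small`` and scales the observed standard deviation by
    ``sqrt(n_small / n_target)`` (root-n convergence of the plug-in
    estimators).
    """
    draws: dict[str, list[float]] = {}
    for i in range(reps):
        ds = simulate_cohort(model, n_small, seed=seed + i)
        for k, r in _estimate_all(ds, plan).items():
            draws.setdefault(k, []).append(r.estimate)
    scale = np.sqrt(n_small / n_target)
    return {k: float(np.std(v, ddof=1)) * scale for k, v in draws.items()}


@pytest.fixture(scope="session")
def toy1_model():
    return toy1()


@pytest.fixture(scope="session")
def toy1_oracle(toy1_model):
    return enumerate_oracle(toy1_model)


@pytest.fixture(scope="session")
def toy1_plan():
    """Saturated outcome model for the canonical Bernoulli SEM."""
    return AnalysisPlan(outcome_terms=saturated_terms(["A", "M"]))


@pytest.fixture(scope="session")
def toy1_cohort_200k(toy1_model):
    return simulate_cohort(toy1_model, 200_000, seed=BASE_SEED)


@pytest.fixture
def small_cohort(toy1_model):
    return simulate_cohort(toy1_model, 4_000, seed=BASE_SEED + 1)


def balanced_binary_table() -> pd.DataFrame:
    """Deterministic table in which M is exactly independent of A.

    Cell counts are chosen so the empirical distribution of M is identical
    in both exposure strata while Y varies with both A and M.
    """
    rows = []
    #          A  M  Y  count
    for a, m, y, k in [(0, 0, 0, 63), (0, 0, 1, 7), (0, 1, 0, 21), (0, 1, 1, 9),
                       (1, 0, 0, 49), (1, 0, 1, 21), (1, 1, 0, 15), (1, 1, 1, 15)]:
        rows += [{"A": a, "M": m, "Y": y}] * k
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_dataset():
    df = balanced_binary_table()
    return StudyDataset(
        df=df, outcome="Y", exposure="A", covariates=(),
        mediator_specs=(MediatorSpec("M", "discrete", (0, 1)),),
        design=StudyDesign("cohort"),
    )
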