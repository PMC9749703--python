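"""Nuisance models: the outcome model and the per-mediator models.

The identification formulas require an outcome model ``P(Y=1 | A, C, M...)``
and, per mediator, either a conditional-mean model ``E[M^k | A, C]``
(continuous mediators) or a level-probability model ``P(M^k = m | A, C)``
(discrete mediators).  Fits are weighted by the dataset's case-control
weights by default, so that in case-control data the models estimate
population quantities; standard errors from these fits are never used —
all inference is via the bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data import MediatorSpec, StudyDataset
from .exceptions import ContractError, EstimationError
from .formulas import DesignBuilder, ModelFormula, Term

logger = logging.getLogger("pspaf")

__all__ = [
    "ModelFormula",
    "Term",
    "FittedOutcomeModel",
    "FittedMediatorModel",
    "fit_outcome_model",
    "fit_mediator_model",
    "shifted_mediator_values",
]

_CLIP = 1e-12


@dataclass
class FittedOutcomeModel:
    """A fitted binary-outcome regression with a frozen design builder.

    ``predict`` evaluates ``P(Y=1 | ...)`` for the records of a DataFrame;
    the ``overrides`` mapping substitutes counterfactual values for named
    columns (e.g. ``{"A": 0}`` or ``{"M": m}``) without copying the data.
    """

    formula: ModelFormula
    builder: DesignBuilder
    coefficients: np.ndarray
    link: str = "logit"
    fit_weights: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame,
                overrides: Mapping[str, object] | None = None) -> np.ndarray:
        X = self.builder.transform(df, overrides)
        eta = X @ self.coefficients
        if self.link == "logit":
            return expit(eta)
        if self.link == "identity":
            p = eta
        elif self.link == "log":
            p = np.exp(eta)
        else:  # pragma: no cover - constructor guards this
            raise ContractError(f"unknown link {self.link!r}")
        n_out = int(np.sum((p < 0) | (p > 1)))
        if n_out:
            logger.warning(
                "%d prediction(s) outside (0,1) clipped under %s link",
                n_out, self.link,
            )
            self.diagnostics["n_clipped"] = self.diagnostics.get("n_clipped", 0) + n_out
        return np.clip(p, _CLIP, 1.0 - _CLIP)


@dataclass
class FittedMediatorModel:
    """Fitted model for one mediator.

    Continuous mediators use a weighted least-squares conditional mean
    ``E[M^k | A, C]``; discrete mediators use a weighted (multinomial)
    logistic model for level probabilities ``P(M^k = m | A, C)``.
    """

    spec: MediatorSpec
    builder: DesignBuilder
    exposure: str
    # continuous:
    coefficients: np.ndarray | None = None
    # discrete:
    _sk_model: object | None = None
    _level_order: tuple | None = None
    fit_weights: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return self.spec.kind

    def predict_mean(self, df: pd.DataFrame, a: float | np.ndarray | None = None,
                     overrides: Mapping[str, object] | None = None) -> np.ndarray:
        """``E[M^k | A=a, C_i]``; ``a=None`` uses each record's observed exposure."""
        if self.kind != "continuous":
            raise ContractError(
                f"predict_mean is for continuous mediators; {self.spec.name!r} "
                "is discrete"
            )
        ov = dict(overrides or {})
        if a is not None:
            ov[self.exposure] = a
        X = self.builder.transform(df, ov)
        return X @ self.coefficients

    def predict_proba(self, df: pd.DataFrame, a: float | np.ndarray | None = None,
                      overrides: Mapping[str, object] | None = None) -> np.ndarray:
        """``P(M^k = m | A=a, C_i)`` as an (n, n_levels) matrix in declared
        level order; rows sum to one."""
        if self.kind != "discrete":
            raise ContractError(
                f"predict_proba is for discrete mediators; {self.spec.name!r} "
                "is continuous"
            )
        ov = dict(overrides or {})
        if a is not None:
            ov[self.exposure] = a
        X = self.builder.transform(df, ov)
        if self.coefficients is not None:  # binary logit
            p1 = expit(X @ self.coefficients)
            probs = np.column_stack([1.0 - p1, p1])
        else:
            raw = self._sk_model.predict_proba(X[:, 1:])  # sklearn adds intercept
            # reorder sklearn's class order to the declared level order
            order = [list(self._sk_model.classes_).index(lv)
                     for lv in self._level_order]
            probs = raw[:, order]
        return probs


def _fit_weighted_logit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                        builder: DesignBuilder) -> tuple[np.ndarray, dict]:
    builder.check_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise EstimationError(f"perfect separation in logistic fit: {exc}") from exc
    if not res.converged:
        raise EstimationError("logistic fit did not converge")
    p = res.fittedvalues
    score0 = float(np.sum(w * (y - p)) / np.sum(w))
    diag = {"converged": bool(res.converged),
            "deviance": float(res.deviance),
            "bse": np.asarray(res.bse),
            "intercept_score_residual": score0}
    if abs(score0) > 1e-6:
        logger.warning("intercept score residual %.3g exceeds 1e-6", score0)
    return np.asarray(res.params), diag


def fit_outcome_model(dataset: StudyDataset, formula: ModelFormula,
                      use_weights: bool = True,
                      link: str = "logit") -> FittedOutcomeModel:
    """Fit the outcome model ``P(Y=1 | terms)`` by weighted maximum likelihood.

    The logit link is the default; identity and log links are experimental
    (their predictions can leave (0,1) and are clipped with a logged warning).
    """
    if formula.response != dataset.outcome:
        raise ContractError(
            f"formula response {formula.response!r} is not the outcome column "
            f"{dataset.outcome!r}"
        )
    w = dataset.weights if use_weights else np.ones(dataset.n)
    builder = DesignBuilder(formula.terms)
    X = builder.fit_transform(dataset.df, w)
    y = dataset.y
    if link == "logit":
        params, diag = _fit_weighted_logit(X, y, w, builder)
    else:
        builder.check_rank(X)
        fam = {"identity": sm.families.Gaussian(),
               "log": sm.families.Poisson()}.get(link)
        if fam is None:
            raise ContractError(f"unsupported link {link!r}")
        logger.warning("link %r is experimental; predictions will be clipped", link)
        res = sm.GLM(y, X, family=fam, freq_weights=w).fit()
        params, diag = np.asarray(res.params), {"converged": True}
    return FittedOutcomeModel(formula=formula, builder=builder,
                              coefficients=params, link=link,
                              fit_weights=w, diagnostics=diag)


def fit_mediator_model(dataset: StudyDataset, spec: MediatorSpec,
                       covariate_terms: Sequence[Term | str] = (),
                       use_weights: bool = True) -> FittedMediatorModel:
    """Fit ``E[M^k | A, C]`` (continuous) or ``P(M^k=m | A, C)`` (discrete).

    The exposure enters as a main-effect term automatically; interactions
    with covariates may be added through ``covariate_terms``.
    """
    if spec.name not in dataset.mediators:
        raise ContractError(f"{spec.name!r} is not a declared mediator")
    terms = [Term(dataset.exposure)] + [
        t if isinstance(t, Term) else Term(t) for t in covariate_terms
    ]
    w = dataset.weights if use_weights else np.ones(dataset.n)
    builder = DesignBuilder(terms)
    X = builder.fit_transform(dataset.df, w)
    builder.check_rank(X)
    m = dataset.df[spec.name].to_numpy()

    if spec.kind == "continuous":
        res = sm.WLS(m.astype(float), X, weights=w).fit()
        return FittedMediatorModel(spec=spec, builder=builder,
                                   exposure=dataset.exposure,
                                   coefficients=np.asarray(res.params),
                                   fit_weights=w,
                                   diagnostics={"bse": np.asarray(res.bse)})

    observed = set(np.unique(m).tolist())
    empty = [lv for lv in spec.levels if lv not in observed]
    if empty:
        raise EstimationError(
            f"mediator {spec.name!r}: declared level(s) {empty} absent from data"
        )
    if len(spec.levels) == 2:
        y = (m == spec.levels[1]).astype(float)
        params, diag = _fit_weighted_logit(X, y, w, builder)
        return FittedMediatorModel(spec=spec, builder=builder,
                                   exposure=dataset.exposure,
                                   coefficients=params, fit_weights=w,
                                   diagnostics=diag)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    clf.fit(X[:, 1:], m, sample_weight=w)  # sklearn adds its own intercept
    if clf.n_iter_.max() >= 2000:
        raise EstimationError(
            f"multinomial fit for {spec.name!r} did not converge"
        )
    return FittedMediatorModel(spec=spec, builder=builder,
                               exposure=dataset.exposure,
                               _sk_model=clf, _level_order=spec.levels,
                               fit_weights=w)


def shifted_mediator_values(dataset: StudyDataset,
                            model: FittedMediatorModel) -> np.ndarray:
    """Exposure-shifted mediator values for a continuous mediator.

    ``Mhat_i = M_i - A_i * (E[M | A=1, C_i] - E[M | A=0, C_i])``: exposed
    records have the fitted exposure-attributable mean difference removed;
    unexposed records are returned unchanged.
    """
    if model.kind != "continuous":
        raise ContractError("shifted_mediator_values requires a continuous mediator")
    m = dataset.df[model.spec.name].to_numpy(dtype=float)
    a = dataset.a
    shift = model.predict_mean(dataset.df, a=1.0) - model.predict_mean(dataset.df, a=0.0)
    return m - a * shift
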