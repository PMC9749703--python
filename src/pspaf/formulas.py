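"""Model terms and design-matrix construction.

Formulas are declared as lists of :class:`Term` objects rather than a
free-text formula language: each term names a column (or a ``":"``-joined
product of numeric columns) and may request a natural cubic spline basis
expansion with a stated number of degrees of freedom.

The spline basis is the classic natural (restricted) cubic spline: cubic
between knots, linear beyond the boundary knots.  Knots are placed at
quantiles of the weighted empirical distribution of the training column
(boundary knots at the observed min/max), so case-control weights influence
knot placement exactly as they influence the fit.  Fitting state (knots,
categorical level sets) is frozen into the builder so that prediction on new
records is deterministic and independent of the prediction batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ConfigurationError, EstimationError

__all__ = ["Term", "ModelFormula", "DesignBuilder", "natural_spline_basis"]


@dataclass(frozen=True)
class Term:
    """One model term.

    ``name`` is a column name, or ``"a:b"`` for the elementwise product of
    two or more numeric columns.  ``spline_df >= 2`` requests a natural cubic
    spline expansion (continuous columns only).  ``categorical`` forces
    indicator coding; by default non-numeric dtypes are coded automatically.
    """

    name: str
    spline_df: int | None = None
    categorical: bool = False

    def __post_init__(self) -> None:
        if self.spline_df is not None:
            if self.spline_df < 2:
                raise ConfigurationError(
                    f"spline_df must be >= 2 for term {self.name!r}"
                )
            if self.categorical or ":" in self.name:
                raise ConfigurationError(
                    f"spline expansion only applies to single continuous "
                    f"columns (term {self.name!r})"
                )


@dataclass(frozen=True)
class ModelFormula:
    """A response column plus a list of terms (intercept always included)."""

    response: str
    terms: tuple[Term, ...]

    def __init__(self, response: str, terms: Sequence[Term | str]):
        object.__setattr__(self, "response", response)
        object.__setattr__(
            self,
            "terms",
            tuple(t if isinstance(t, Term) else Term(t) for t in terms),
        )


def _weighted_quantile(x: np.ndarray, q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Quantiles of the weighted empirical distribution (inverse-CDF type)."""
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cdf = np.cumsum(ws) / ws.sum()
    return xs[np.searchsorted(cdf, q, side="left").clip(0, len(xs) - 1)]


def spline_knots(x: np.ndarray, df: int, weights: np.ndarray | None = None) -> np.ndarray:
    """Knot vector for a df-dimensional natural cubic spline basis.

    ``df + 1`` knots in total: boundary knots at min/max and ``df - 1``
    interior knots at evenly spaced weighted quantiles.
    """
    x = np.asarray(x, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    interior_q = np.arange(1, df) / df
    interior = _weighted_quantile(x, interior_q, w)
    knots = np.concatenate([[x.min()], interior, [x.max()]])
    if len(np.unique(knots)) != len(knots):
        raise EstimationError(
            f"natural-spline knots are not distinct ({knots}); "
            "reduce spline_df or check the column for ties"
        )
    return knots


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    With ``K`` knots the basis has ``K - 1`` columns: the identity plus
    ``K - 2`` restricted truncated-power functions, giving a function space
    that is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k: int) -> np.ndarray:
        # (x - knot_k)_+^3 - (x - knot_{K-1})_+^3, scaled
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


class DesignBuilder:
    """Builds design matrices from a term list, with frozen fit-time state.

    ``fit`` records spline knots and categorical level sets from the training
    data; ``transform`` then produces the matrix for any record batch.  The
    ``overrides`` mapping substitutes values for named columns without
    copying the DataFrame (used to evaluate counterfactual predictions such
    as ``A = 0`` or ``M^k = m``).
    """

    def __init__(self, terms: Sequence[Term]):
        self.terms = tuple(terms)
        self._state: dict[str, object] = {}
        self.columns: list[str] = []
        self._fitted = False

    # -- fitting ---------------------------------------------------------------
    def fit(self, df: pd.DataFrame, weights: np.ndarray | None = None) -> "DesignBuilder":
        self._state.clear()
        self.columns = ["Intercept"]
        for term in self.terms:
            for col in term.name.split(":"):
                if col not in df.columns:
                    raise ConfigurationError(f"term column {col!r} not in data")
            if term.spline_df is not None:
                x = df[term.name].to_numpy(dtype=float)
                knots = spline_knots(x, term.spline_df, weights)
                self._state[term.name] = ("spline", knots)
                self.columns += [f"ns({term.name},{term.spline_df}).{j}"
                                 for j in range(term.spline_df)]
            elif ":" in term.name:
                self._state[term.name] = ("numeric", None)
                self.columns.append(term.name)
            elif term.categorical or self._is_categorical(df[term.name]):
                levels = sorted(pd.unique(df[term.name]).tolist())
                if len(levels) < 2:
                    raise EstimationError(
                        f"categorical term {term.name!r} has a single level"
                    )
                self._state[term.name] = ("categorical", levels)
                self.columns += [f"{term.name}[{lv}]" for lv in levels[1:]]
            else:
                self._state[term.name] = ("numeric", None)
                self.columns.append(term.name)
        self._fitted = True
        return self

    @staticmethod
    def _is_categorical(col: pd.Series) -> bool:
        return col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ) or col.dtype == bool

    # -- transformation ----------------------------------------------------------
    def _column(self, df: pd.DataFrame, name: str,
                overrides: Mapping[str, object] | None) -> np.ndarray:
        if overrides and name in overrides:
            val = overrides[name]
            arr = np.asarray(val, dtype=float)
            if arr.ndim == 0:
                arr = np.full(len(df), float(arr))
            return arr
        return df[name].to_numpy()

    def transform(self, df: pd.DataFrame,
                  overrides: Mapping[str, object] | None = None) -> np.ndarray:
        if not self._fitted:
            raise EstimationError("DesignBuilder.transform called before fit")
        n = len(df)
        blocks = [np.ones((n, 1))]
        for term in self.terms:
            kind, state = self._state[term.name]
            if kind == "spline":
                x = self._column(df, term.name, overrides).astype(float)
                blocks.append(natural_spline_basis(x, state))
            elif kind == "categorical":
                x = self._column(df, term.name, overrides)
                levels = state
                blocks.append(np.column_stack([(x == lv).astype(float)
                                               for lv in levels[1:]]))
            else:
                cols = term.name.split(":")
                x = self._column(df, cols[0], overrides).astype(float)
                for extra in cols[1:]:
                    x = x * self._column(df, extra, overrides).astype(float)
                blocks.append(x[:, None])
        return np.concatenate(blocks, axis=1)

    def fit_transform(self, df: pd.DataFrame,
                      weights: np.ndarray | None = None) -> np.ndarray:
        return self.fit(df, weights).transform(df)

    # -- diagnostics -------------------------------------------------------------
    def check_rank(self, X: np.ndarray) -> None:
        """Raise naming (near-)collinear columns if X is rank deficient."""
        _, r, pivots = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [self.columns[p] for p, v in zip(pivots, diag) if v < tol]
        if bad:
            raise EstimationError(
                f"design matrix is rank deficient; collinear terms: {bad}"
            )
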