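"""Datasets, study designs, mediator declarations and case-control weights.

The central container is :class:`StudyDataset`: a validated, complete-case
table of one binary outcome ``Y``, one binary exposure ``A``, baseline
covariates ``C``, one or more mediators ``M^1..M^K`` and a per-record weight
``w_i``.  Weights implement the standard case-control reweighting: cases get
weight 1 and controls get ``(1/pi - 1)/r`` where ``pi`` is the population
disease prevalence and ``1:r`` the case:control matching ratio, so that the
weighted sample mimics the source population.  Cohort and cross-sectional
designs use unit weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    ValidationError,
)

logger = logging.getLogger("pspaf")

__all__ = [
    "StudyDesign",
    "MediatorSpec",
    "StudyDataset",
    "compute_weights",
    "validate_dataset",
    "load_config",
    "dataset_from_config",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the study.

    Parameters
    ----------
    kind:
        ``"cohort"``, ``"cross_sectional"`` or ``"case_control"``.
    prevalence:
        Population disease prevalence ``pi``; required for (and only
        meaningful in) case-control designs.
    matching_ratio:
        Case:control matching ratio ``r`` (``1:r``); if ``None`` for a
        case-control design, the realized control/case ratio of the analyzed
        sample is used.
    """

    kind: str
    prevalence: float | None = None
    matching_ratio: float | None = None

    _KINDS = ("cohort", "cross_sectional", "case_control")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigurationError(
                f"unknown design kind {self.kind!r}; expected one of {self._KINDS}"
            )
        if self.kind == "case_control":
            if self.prevalence is None:
                raise ConfigurationError("case_control design requires a prevalence")
            if not 0.0 < self.prevalence < 1.0:
                raise ConfigurationError(
                    f"prevalence must lie in (0, 1); got {self.prevalence}"
                )
            if self.matching_ratio is not None and self.matching_ratio < 1:
                raise ConfigurationError(
                    f"matching ratio must be >= 1; got {self.matching_ratio}"
                )
        else:
            if self.prevalence is not None or self.matching_ratio is not None:
                raise ConfigurationError(
                    "prevalence / matching_ratio are only valid for case_control designs"
                )


@dataclass(frozen=True)
class MediatorSpec:
    """Declaration of a single mediator column.

    ``d_separated`` asserts that this mediator lies on a causal pathway
    separate from the other declared mediators given exposure and covariates;
    the joint-outcome-model estimators require it for every mediator.
    """

    name: str
    kind: str  # "continuous" | "discrete"
    levels: tuple | None = None
    d_separated: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ConfigurationError(
                f"mediator kind must be 'continuous' or 'discrete'; got {self.kind!r}"
            )
        if self.kind == "discrete":
            if self.levels is None or len(self.levels) < 2:
                raise ConfigurationError(
                    f"discrete mediator {self.name!r} needs >= 2 declared levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels is not None:
            raise ConfigurationError(
                f"continuous mediator {self.name!r} must not declare levels"
            )


@dataclass
class StudyDataset:
    """Validated individual-level data with attached design and weights."""

    df: pd.DataFrame
    outcome: str
    exposure: str
    covariates: tuple[str, ...]
    mediator_specs: tuple[MediatorSpec, ...]
    design: StudyDesign
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = compute_weights(
                self.df[self.outcome].to_numpy(), self.design
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.df):
            raise ValidationError("weights length does not match record count")
        if np.any(self.weights <= 0):
            raise ValidationError("all weights must be strictly positive")

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.outcome].to_numpy(dtype=float)

    @property
    def a(self) -> np.ndarray:
        return self.df[self.exposure].to_numpy(dtype=float)

    @property
    def mediators(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.mediator_specs)

    def spec(self, name: str) -> MediatorSpec:
        for s in self.mediator_specs:
            if s.name == name:
                return s
        raise ConfigurationError(f"no mediator named {name!r} is declared")

    def subset(self, idx: np.ndarray) -> "StudyDataset":
        """Row subset (e.g. a bootstrap resample); weights recomputed from design."""
        sub = self.df.iloc[idx].reset_index(drop=True)
        return replace(self, df=sub, weights=compute_weights(
            sub[self.outcome].to_numpy(), self.design))

    def validation_report(self, dropped: int = 0) -> dict:
        """JSON-serializable summary of record counts and weights."""
        y = self.y
        return {
            "n_records": int(self.n),
            "n_dropped": int(dropped),
            "n_cases": int(y.sum()),
            "n_exposed": int(self.a.sum()),
            "design": self.design.kind,
            "weight_min": float(self.weights.min()),
            "weight_max": float(self.weights.max()),
            "weighted_case_fraction": float(
                (self.weights * y).sum() / self.weights.sum()
            ),
        }


def compute_weights(y: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Per-record weights for the given design.

    Cohort / cross-sectional: ``w_i = 1``.  Case-control: ``w_i = 1`` for
    cases and ``w_i = (1/pi - 1)/r`` for controls, which reconstructs the
    source population when cases and controls are random samples of their
    strata.  If no matching ratio was supplied, ``r`` defaults to the
    realized control:case ratio of the sample.
    """
    y = np.asarray(y, dtype=float)
    if design.kind != "case_control":
        return np.ones(len(y))
    n_cases = y.sum()
    if n_cases == 0 or n_cases == len(y):
        raise DegenerateDataError("case-control data need both cases and controls")
    r = design.matching_ratio
    if r is None:
        r = (len(y) - n_cases) / n_cases
    w_control = (1.0 / design.prevalence - 1.0) / r
    if w_control <= 0:
        raise ConfigurationError("control weight (1/pi - 1)/r must be positive")
    return np.where(y == 1.0, 1.0, w_control)


def _check_binary(values: pd.Series, column: str) -> None:
    bad = sorted(set(np.unique(values).tolist()) - {0, 1})
    if bad:
        raise ValidationError(
            f"column {column!r} must be binary 0/1; found values {bad}"
        )


def validate_dataset(
    raw_table: pd.DataFrame,
    roles: Mapping[str, object],
    specs: Sequence[MediatorSpec],
    design: StudyDesign,
) -> StudyDataset:
    """Validate a raw table and return a complete-case :class:`StudyDataset`.

    ``roles`` maps ``outcome`` and ``exposure`` to column names and
    ``covariates`` to a (possibly empty) list of column names.  Mediator
    columns come from ``specs``.  Records with a missing value in any used
    column are dropped (complete-case analysis); the dropped count is logged.
    """
    try:
        outcome = str(roles["outcome"])
        exposure = str(roles["exposure"])
    except KeyError as exc:
        raise ConfigurationError(f"roles mapping is missing {exc.args[0]!r}") from exc
    covariates = tuple(str(c) for c in roles.get("covariates", ()))
    if not specs:
        raise ConfigurationError("at least one mediator must be declared")

    used = [outcome, exposure, *covariates, *[s.name for s in specs]]
    missing = [c for c in used if c not in raw_table.columns]
    if missing:
        raise ConfigurationError(f"columns not found in the data: {missing}")
    if len(set(used)) != len(used):
        raise ConfigurationError(f"column roles overlap: {used}")

    df = raw_table.loc[:, used].copy()
    before = len(df)
    df = df.dropna().reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d record(s) with missing values", dropped)
    if len(df) == 0:
        raise DegenerateDataError("no complete-case records remain")

    _check_binary(df[outcome], outcome)
    _check_binary(df[exposure], exposure)

    for spec in specs:
        if spec.kind == "discrete":
            observed = set(np.unique(df[spec.name]).tolist())
            extra = observed - set(spec.levels)
            if extra:
                raise ValidationError(
                    f"mediator {spec.name!r} has values {sorted(extra)} outside "
                    f"its declared levels {list(spec.levels)}"
                )

    a = df[exposure].to_numpy()
    y = df[outcome].to_numpy()
    if a.sum() == 0 or a.sum() == len(df):
        raise DegenerateDataError("need at least one exposed and one unexposed record")
    if y.sum() == 0:
        raise DegenerateDataError("need at least one case (Y=1)")

    ds = StudyDataset(
        df=df,
        outcome=outcome,
        exposure=exposure,
        covariates=covariates,
        mediator_specs=tuple(specs),
        design=design,
    )
    logger.info("validation report: %s", json.dumps(ds.validation_report(dropped)))
    return ds


# ---------------------------------------------------------------------------
# config-file front end (used by the CLI and by scripted analyses)
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def _design_from_config(cfg: Mapping) -> StudyDesign:
    return StudyDesign(
        kind=cfg["kind"],
        prevalence=cfg.get("prevalence"),
        matching_ratio=cfg.get("matching_ratio"),
    )


def _specs_from_config(entries: Sequence[Mapping]) -> list[MediatorSpec]:
    specs = []
    for e in entries:
        specs.append(
            MediatorSpec(
                name=e["name"],
                kind=e["kind"],
                levels=tuple(e["levels"]) if e.get("levels") is not None else None,
                d_separated=bool(e.get("d_separated", True)),
            )
        )
    return specs


def dataset_from_config(cfg: Mapping, data_path: str | Path | None = None) -> StudyDataset:
    """Build a :class:`StudyDataset` from a parsed run configuration.

    Expected keys: ``input`` (CSV/TSV path, unless ``data_path`` overrides),
    ``outcome``, ``exposure``, ``covariates``, ``mediators`` (list of
    ``{name, kind, levels?, d_separated?}``) and ``design``
    (``{kind, prevalence?, matching_ratio?}``).
    """
    path = Path(data_path if data_path is not None else cfg["input"])
    if not path.exists():
        raise ConfigurationError(f"input data file not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    roles = {
        "outcome": cfg["outcome"],
        "exposure": cfg["exposure"],
        "covariates": cfg.get("covariates", []),
    }
    specs = _specs_from_config(cfg["mediators"])
    design = _design_from_config(cfg["design"])
    return validate_dataset(raw, roles, specs, design)
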