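"""Structural-equation simulator and ground-truth oracle.

Models are non-parametric structural equation models with independent errors
(NPSEM-IE) over covariates ``C``, a binary exposure ``A``, mediators
``M^1..M^K`` and a binary outcome ``Y``.  Each node carries an independent
exogenous noise variable and a deterministic assignment function of its
parents and that noise; counterfactuals are evaluated by substituting
interventions into the assignment functions while *sharing* the noise across
worlds, so cross-world quantities such as ``Y_{A, M_0^k}`` are well defined.

Two oracles are provided:

* :func:`enumerate_oracle` — exact summation over the joint support for
  all-discrete models.  Exogenous noise is enumerated by partitioning each
  node's uniform noise into the intervals induced by the cumulative
  assignment probabilities across every parent configuration, which makes
  the enumeration exact rather than a fine-grid approximation.
* :func:`mc_oracle` — seeded Monte Carlo with shared noise for models
  containing continuous (Gaussian) nodes, reporting its own Monte-Carlo
  standard errors (outcome probabilities are averaged conditionally on the
  outcome's parents, i.e. Rao-Blackwellized).

The module also generates study data: i.i.d. cohorts, 1:r case-control
samples drawn from the conditional laws given case status, and a synthetic
stroke-study generator with a rare outcome, one binary and two continuous
mediators, and case-control sampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.optimize import brentq
from scipy.special import expit

from .data import MediatorSpec, StudyDataset, StudyDesign
from .exceptions import (
    ConfigurationError,
    ContractError,
    DegenerateDataError,
    ResourceError,
    UnsupportedStructureError,
)

__all__ = [
    "DiscreteNode",
    "GaussianNode",
    "StructuralModel",
    "OracleFunctionals",
    "bernoulli_node",
    "tabular_node",
    "enumerate_oracle",
    "mc_oracle",
    "verify_identification_equivalence",
    "simulate_cohort",
    "sample_case_control",
    "toy1",
    "two_mediator_toy",
    "random_logistic_sem",
    "random_monotone_sem",
    "make_interstroke_like",
    "model_to_dict",
    "model_from_dict",
]


# ---------------------------------------------------------------------------
# nodes and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteNode:
    """Finite-support node.

    ``prob_fn(parent_values, n)`` returns an ``(n, n_levels)`` matrix of
    conditional level probabilities given arrays of parent values.  The
    assignment function is the inverse CDF applied to the node's uniform
    noise, so identical noise plus identical parents gives identical values
    across counterfactual worlds.
    """

    name: str
    levels: tuple
    parents: tuple[str, ...] = ()
    prob_fn: Callable[[Mapping[str, np.ndarray], int], np.ndarray] = None


@dataclass(frozen=True)
class GaussianNode:
    """Continuous node: value = mean_fn(parents) + sd * z, z ~ N(0,1)."""

    name: str
    parents: tuple[str, ...] = ()
    mean_fn: Callable[[Mapping[str, np.ndarray], int], np.ndarray] = None
    sd: float = 1.0


def bernoulli_node(name: str, parents: Sequence[str],
                   p_fn: Callable[[Mapping[str, np.ndarray]], np.ndarray]) -> DiscreteNode:
    """Binary node with success probability ``p_fn(parent_values)``."""

    def prob_fn(vals: Mapping[str, np.ndarray], n: int) -> np.ndarray:
        p = np.clip(np.broadcast_to(np.asarray(p_fn(vals), dtype=float), (n,)), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])

    return DiscreteNode(name, (0, 1), tuple(parents), prob_fn)


def tabular_node(name: str, levels: Sequence, parents: Sequence[str],
                 parent_levels: Sequence[Sequence],
                 table: Mapping[tuple, Sequence[float]]) -> DiscreteNode:
    """Discrete node from an explicit conditional probability table.

    ``table`` maps each tuple of parent values (in ``parents`` order) to a
    probability vector over ``levels``.  Used by the YAML model format.
    """
    levels = tuple(levels)
    parents = tuple(parents)
    lookup = {tuple(k): np.asarray(v, dtype=float) for k, v in table.items()}
    for k, v in lookup.items():
        if abs(v.sum() - 1.0) > 1e-10 or np.any(v < 0):
            raise ConfigurationError(
                f"node {name!r}: probabilities for parents {k} are not a "
                f"distribution: {v.tolist()}"
            )

    def prob_fn(vals: Mapping[str, np.ndarray], n: int) -> np.ndarray:
        if not parents:
            return np.broadcast_to(lookup[()], (n, len(levels)))
        cols = [np.broadcast_to(np.asarray(vals[p]), (n,)) for p in parents]
        out = np.empty((n, len(levels)))
        keys = list(zip(*[c.tolist() for c in cols]))
        for i, key in enumerate(keys):
            out[i] = lookup[key]
        return out

    return DiscreteNode(name, levels, parents, prob_fn)


@dataclass
class StructuralModel:
    """An NPSEM-IE over (C, A, M^1..M^K, Y) with declared variable roles.

    ``nodes`` must be in topological order (every parent precedes its child);
    ``mediator_structure`` is ``"d_separated"`` when mediators lie on
    separate causal pathways given A and C, or ``"sequential"`` when one
    mediator may be a parent of another.
    """

    nodes: tuple
    covariates: tuple[str, ...]
    exposure: str
    mediators: tuple[str, ...]
    outcome: str
    mediator_structure: str = "d_separated"
    name: str | None = None
    true_prevalence: float | None = None

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate node names")
        seen: set[str] = set()
        for nd in self.nodes:
            for p in nd.parents:
                if p not in seen:
                    raise ConfigurationError(
                        f"node {nd.name!r} has parent {p!r} that does not "
                        "precede it (model must be acyclic and topologically "
                        "ordered)"
                    )
            seen.add(nd.name)
        for role_name in (self.exposure, self.outcome, *self.covariates, *self.mediators):
            if role_name not in names:
                raise ConfigurationError(f"role refers to unknown node {role_name!r}")
        ynode = self.node(self.outcome)
        if not isinstance(ynode, DiscreteNode) or tuple(ynode.levels) != (0, 1):
            raise ConfigurationError("outcome node must be binary with levels (0, 1)")
        anode = self.node(self.exposure)
        if not isinstance(anode, DiscreteNode) or tuple(anode.levels) != (0, 1):
            raise ConfigurationError("exposure node must be binary with levels (0, 1)")
        if self.mediator_structure not in ("d_separated", "sequential"):
            raise ConfigurationError(
                f"unknown mediator_structure {self.mediator_structure!r}"
            )

    def node(self, name: str):
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(name)

    @property
    def all_discrete(self) -> bool:
        return all(isinstance(nd, DiscreteNode) for nd in self.nodes)

    def mediator_specs(self) -> tuple[MediatorSpec, ...]:
        specs = []
        for m in self.mediators:
            nd = self.node(m)
            if isinstance(nd, DiscreteNode):
                specs.append(MediatorSpec(m, "discrete", tuple(nd.levels),
                                          d_separated=self.mediator_structure == "d_separated"))
            else:
                specs.append(MediatorSpec(m, "continuous",
                                          d_separated=self.mediator_structure == "d_separated"))
        return tuple(specs)


# ---------------------------------------------------------------------------
# sampling and counterfactual evaluation (vectorized, shared noise)
# ---------------------------------------------------------------------------

def _sample_noise(model: StructuralModel, n: int, rng) -> dict[str, np.ndarray]:
    noise = {}
    for nd in model.nodes:
        if isinstance(nd, DiscreteNode):
            noise[nd.name] = rng.random(n)
        else:
            noise[nd.name] = rng.standard_normal(n)
    return noise


def _assign(nd, parent_vals: Mapping[str, np.ndarray], u: np.ndarray, n: int) -> np.ndarray:
    if isinstance(nd, DiscreteNode):
        cum = np.cumsum(nd.prob_fn(parent_vals, n), axis=1)
        idx = np.minimum(np.sum(u[:, None] >= cum, axis=1), len(nd.levels) - 1)
        return np.asarray(nd.levels)[idx]
    mean = np.broadcast_to(np.asarray(nd.mean_fn(parent_vals, n), dtype=float), (n,))
    return mean + nd.sd * u


def _evaluate(model: StructuralModel, noise: Mapping[str, np.ndarray],
              interventions: Mapping[str, object], n: int,
              skip_outcome: bool = False) -> dict[str, np.ndarray]:
    """One counterfactual world: recursive substitution with shared noise."""
    vals: dict[str, np.ndarray] = {}
    for nd in model.nodes:
        if skip_outcome and nd.name == model.outcome:
            continue
        if nd.name in interventions:
            v = np.asarray(interventions[nd.name])
            vals[nd.name] = np.broadcast_to(v, (n,)) if v.ndim == 0 else v
        else:
            parent_vals = {p: vals[p] for p in nd.parents}
            vals[nd.name] = _assign(nd, parent_vals, noise[nd.name], n)
    return vals


def _p_outcome(model: StructuralModel, world: Mapping[str, np.ndarray],
               n: int) -> np.ndarray:
    """P(Y=1 | parents) per record — Rao-Blackwellized outcome probability."""
    ynode = model.node(model.outcome)
    parent_vals = {p: world[p] for p in ynode.parents}
    return ynode.prob_fn(parent_vals, n)[:, 1]


# ---------------------------------------------------------------------------
# oracle functionals
# ---------------------------------------------------------------------------

@dataclass
class OracleFunctionals:
    """Counterfactual functionals of a structural model and the PAFs they imply.

    ``p_interventional[k]`` is ``P(Y_{A, G_{0|C}^k} = 1)`` (mediator drawn
    afresh from its conditional law under exposure elimination),
    ``p_mechanistic[k]`` is ``P(Y_{A, M_0^k} = 1)`` (the individual's own
    counterfactual mediator, shared noise), and ``p_identification[k]`` is
    the observational identification formula
    ``E_{A,C} E_{M^k|A=0,C} P(Y=1 | A, C, M^k)``; the three coincide for
    d-separated mediators.
    """

    p_y: float
    p_y0: float
    p_direct_all: float
    p_interventional: dict[str, float]
    p_mechanistic: dict[str, float]
    p_direct: dict[str, float]
    p_identification: dict[str, float] | None = None
    se: dict[str, float] = field(default_factory=dict)
    method: str = "enumeration"
    n_draws: int | None = None

    # -- derived attributable fractions ---------------------------------------
    @property
    def paf_total(self) -> float:
        return (self.p_y - self.p_y0) / self.p_y

    @property
    def paf_direct_all(self) -> float:
        return (self.p_y - self.p_direct_all) / self.p_y

    def ps_paf(self, k: str) -> float:
        return (self.p_y - self.p_interventional[k]) / self.p_y

    def paf_direct(self, k: str) -> float:
        return (self.p_y - self.p_direct[k]) / self.p_y

    def paf_indirect(self, k: str) -> float:
        return self.paf_total - self.paf_direct(k)

    def as_dict(self) -> dict:
        d = {
            "p_y": self.p_y,
            "p_y0": self.p_y0,
            "paf_total": self.paf_total,
            "paf_direct_all": self.paf_direct_all,
            "method": self.method,
        }
        for k in self.p_interventional:
            d[f"ps_paf[{k}]"] = self.ps_paf(k)
            d[f"paf_direct[{k}]"] = self.paf_direct(k)
            d[f"paf_indirect[{k}]"] = self.paf_indirect(k)
        return d


# -- exact enumeration --------------------------------------------------------

def _noise_atoms(model: StructuralModel, nd: DiscreteNode,
                 supports: Mapping[str, tuple]) -> list[tuple[float, float]]:
    """Partition the node's uniform noise into exact atoms.

    The inverse-CDF assignment only compares the noise against cumulative
    probabilities, so splitting [0,1) at every cumulative probability that
    arises across every parent configuration yields intervals on which the
    assignment is constant in each world.  Returns (probability, midpoint)
    pairs.
    """
    thresholds = {0.0, 1.0}
    parent_supps = [supports[p] for p in nd.parents]
    for cfg in itertools.product(*parent_supps):
        vals = {p: np.asarray([v]) for p, v in zip(nd.parents, cfg)}
        cum = np.cumsum(nd.prob_fn(vals, 1)[0])
        thresholds.update(float(c) for c in cum if 0.0 < c < 1.0)
    cuts = np.array(sorted(thresholds))
    keep = np.concatenate([[True], np.diff(cuts) > 1e-14])
    cuts = cuts[keep]
    return [(hi - lo, (lo + hi) / 2.0) for lo, hi in zip(cuts[:-1], cuts[1:])]


def _values_under_scalar(model: StructuralModel, us: Mapping[str, float],
                         interventions: Mapping[str, object]) -> dict:
    """Scalar world evaluation used by the enumeration oracle."""
    vals: dict = {}
    for nd in model.nodes:
        if nd.name == model.outcome:
            continue
        if nd.name in interventions:
            vals[nd.name] = interventions[nd.name]
            continue
        parent_vals = {p: np.asarray([vals[p]]) for p in nd.parents}
        cum = np.cumsum(nd.prob_fn(parent_vals, 1)[0])
        u = us[nd.name]
        idx = min(int(np.sum(u >= cum)), len(nd.levels) - 1)
        vals[nd.name] = nd.levels[idx]
    return vals


def _py_scalar(model: StructuralModel, vals: Mapping) -> float:
    ynode = model.node(model.outcome)
    parent_vals = {p: np.asarray([vals[p]]) for p in ynode.parents}
    return float(ynode.prob_fn(parent_vals, 1)[0, 1])


def _m0_given_c(model: StructuralModel, k: str,
                supports: Mapping[str, tuple],
                atoms: Mapping[str, list]) -> dict[tuple, np.ndarray]:
    """P(M_0^k = m | C = c) for every covariate configuration, exactly."""
    mk_levels = tuple(model.node(k).levels)
    inner = [nd.name for nd in model.nodes
             if nd.name not in model.covariates and nd.name != model.outcome
             and nd.name != model.exposure]
    out: dict[tuple, np.ndarray] = {}
    cov_supports = [supports[c] for c in model.covariates]
    for ccfg in itertools.product(*cov_supports):
        interv = dict(zip(model.covariates, ccfg))
        interv[model.exposure] = 0
        dist = np.zeros(len(mk_levels))
        for combo in itertools.product(*[atoms[nm] for nm in inner]):
            pw = 1.0
            us = {}
            for nm, (p, u) in zip(inner, combo):
                pw *= p
                us[nm] = u
            vals = _values_under_scalar(model, us, interv)
            dist[mk_levels.index(vals[k])] += pw
        out[ccfg] = dist
    return out


def enumerate_oracle(model: StructuralModel,
                     max_worlds: float = 1e7) -> OracleFunctionals:
    """Exact counterfactual functionals of an all-discrete model.

    Sums over the exact joint distribution of the exogenous noise (see
    :func:`_noise_atoms`), evaluating counterfactuals by recursive
    substitution with shared noise across worlds.  The outcome's own noise is
    integrated out analytically.
    """
    if not model.all_discrete:
        raise UnsupportedStructureError(
            "exact enumeration requires finite support at every node; "
            "use mc_oracle for models with continuous nodes"
        )
    supports = {nd.name: tuple(nd.levels) for nd in model.nodes}
    inner_names = [nd.name for nd in model.nodes if nd.name != model.outcome]
    atoms = {nd.name: _noise_atoms(model, nd, supports)
             for nd in model.nodes if nd.name != model.outcome}
    n_worlds = float(np.prod([len(atoms[nm]) for nm in inner_names]))
    if n_worlds > max_worlds:
        raise ResourceError(
            f"enumeration would visit {n_worlds:.3g} noise configurations "
            f"(limit {max_worlds:.3g})"
        )

    m0_dists = {k: _m0_given_c(model, k, supports, atoms) for k in model.mediators}

    A, Y = model.exposure, model.outcome
    p_y = p_y0 = p_direct_all = 0.0
    p_mech = {k: 0.0 for k in model.mediators}
    p_int = {k: 0.0 for k in model.mediators}
    p_dir = {k: 0.0 for k in model.mediators}
    # observational tables for the identification formula:
    mass: dict[str, dict] = {k: {} for k in model.mediators}
    mass_y: dict[str, dict] = {k: {} for k in model.mediators}

    for combo in itertools.product(*[atoms[nm] for nm in inner_names]):
        pw = 1.0
        us = {}
        for nm, (p, u) in zip(inner_names, combo):
            pw *= p
            us[nm] = u
        nat = _values_under_scalar(model, us, {})
        w0 = _values_under_scalar(model, us, {A: 0})
        p_y += pw * _py_scalar(model, nat)
        p_y0 += pw * _py_scalar(model, w0)
        direct_interv = {A: 0, **{m: nat[m] for m in model.mediators}}
        p_direct_all += pw * _py_scalar(
            model, _values_under_scalar(model, us, direct_interv))
        ccfg = tuple(nat[c] for c in model.covariates)
        for k in model.mediators:
            mech = _values_under_scalar(model, us, {k: w0[k]})
            p_mech[k] += pw * _py_scalar(model, mech)
            dirk = _values_under_scalar(model, us, {A: 0, k: nat[k]})
            p_dir[k] += pw * _py_scalar(model, dirk)
            dist = m0_dists[k][ccfg]
            for q, m in zip(dist, model.node(k).levels):
                if q == 0.0:
                    continue
                wint = _values_under_scalar(model, us, {k: m})
                p_int[k] += pw * q * _py_scalar(model, wint)
            key = (ccfg, nat[A], nat[k])
            mass[k][key] = mass[k].get(key, 0.0) + pw
            mass_y[k][key] = mass_y[k].get(key, 0.0) + pw * _py_scalar(model, nat)

    # identification formula E_{A,C} E_{Mk|A=0,C} P(Y=1|A,C,Mk) from the
    # observational joint law
    p_ident = {}
    for k in model.mediators:
        mk_levels = tuple(model.node(k).levels)
        # P(Mk=m | A=0, C=c)
        stratum0 = {}
        for (ccfg, a, m), p in mass[k].items():
            if a == 0:
                stratum0.setdefault(ccfg, np.zeros(len(mk_levels)))
                stratum0[ccfg][mk_levels.index(m)] += p
        total = 0.0
        # group P(A=a, C=c)
        pac: dict = {}
        for (ccfg, a, m), p in mass[k].items():
            pac[(ccfg, a)] = pac.get((ccfg, a), 0.0) + p
        for (ccfg, a), p_ac in pac.items():
            q0 = stratum0.get(ccfg)
            if q0 is None or q0.sum() == 0.0:
                raise DegenerateDataError(
                    f"positivity violated: no mass at A=0 within C={ccfg}"
                )
            q0 = q0 / q0.sum()
            for q, m in zip(q0, mk_levels):
                if q == 0.0:
                    continue
                num = mass_y[k].get((ccfg, a, m), 0.0)
                den = mass[k].get((ccfg, a, m), 0.0)
                if den == 0.0:
                    raise DegenerateDataError(
                        f"positivity violated: P({k}={m} | A={a}, C={ccfg}) = 0 "
                        "but the identification formula requires this stratum"
                    )
                total += p_ac * q * (num / den)
        p_ident[k] = total

    return OracleFunctionals(
        p_y=p_y, p_y0=p_y0, p_direct_all=p_direct_all,
        p_interventional=p_int, p_mechanistic=p_mech, p_direct=p_dir,
        p_identification=p_ident, method="enumeration",
    )


# -- Monte Carlo oracle --------------------------------------------------------

def _ratio_se(num_i: np.ndarray, den_i: np.ndarray) -> float:
    """Delta-method SE for mean(num_i) / mean(den_i)."""
    n = len(num_i)
    nbar, dbar = num_i.mean(), den_i.mean()
    infl = num_i / dbar - nbar * den_i / dbar**2
    return float(infl.std(ddof=1) / np.sqrt(n))


def mc_oracle(model: StructuralModel, n_draws: int = 1_000_000,
              seed: int = 0) -> OracleFunctionals:
    """Monte-Carlo counterfactual functionals with shared exogenous noise.

    Works for models with continuous nodes.  Per-functional and per-PAF
    Monte-Carlo standard errors are reported in ``.se`` (delta method for
    the PAF ratios).
    """
    rng = default_rng(seed)
    n = int(n_draws)
    noise = _sample_noise(model, n, rng)
    A = model.exposure

    nat = _evaluate(model, noise, {}, n, skip_outcome=True)
    w0 = _evaluate(model, noise, {A: 0}, n, skip_outcome=True)
    py_i = _p_outcome(model, nat, n)
    py0_i = _p_outcome(model, w0, n)
    dall = _evaluate(model, noise,
                     {A: 0, **{m: nat[m] for m in model.mediators}},
                     n, skip_outcome=True)
    pdall_i = _p_outcome(model, dall, n)

    se: dict[str, float] = {
        "p_y": float(py_i.std(ddof=1) / np.sqrt(n)),
        "paf_total": _ratio_se(py_i - py0_i, py_i),
        "paf_direct_all": _ratio_se(py_i - pdall_i, py_i),
    }
    p_int, p_mech, p_dir = {}, {}, {}
    for k in model.mediators:
        mech = _evaluate(model, noise, {k: w0[k]}, n, skip_outcome=True)
        pmech_i = _p_outcome(model, mech, n)
        # fresh mediator noise + exposure elimination => independent draw
        # from the conditional law of M_0^k given C
        noise_g = dict(noise)
        for m in model.mediators:
            nd = model.node(m)
            noise_g[m] = (rng.random(n) if isinstance(nd, DiscreteNode)
                          else rng.standard_normal(n))
        g = _evaluate(model, noise_g, {A: 0}, n, skip_outcome=True)[k]
        wint = _evaluate(model, noise, {k: g}, n, skip_outcome=True)
        pint_i = _p_outcome(model, wint, n)
        dirk = _evaluate(model, noise, {A: 0, k: nat[k]}, n, skip_outcome=True)
        pdir_i = _p_outcome(model, dirk, n)
        p_int[k] = float(pint_i.mean())
        p_mech[k] = float(pmech_i.mean())
        p_dir[k] = float(pdir_i.mean())
        se[f"ps_paf[{k}]"] = _ratio_se(py_i - pint_i, py_i)
        se[f"paf_direct[{k}]"] = _ratio_se(py_i - pdir_i, py_i)
        se[f"paf_indirect[{k}]"] = _ratio_se(pdir_i - py0_i, py_i)

    return OracleFunctionals(
        p_y=float(py_i.mean()), p_y0=float(py0_i.mean()),
        p_direct_all=float(pdall_i.mean()),
        p_interventional=p_int, p_mechanistic=p_mech, p_direct=p_dir,
        se=se, method="monte_carlo", n_draws=n,
    )


def verify_identification_equivalence(model: StructuralModel,
                                      tol: float = 1e-12) -> dict:
    """Check that interventional, mechanistic and identification-formula
    functionals coincide.

    For d-separated mediators the three must agree (this is asserted to
    ``tol`` and a violation raises); for sequential mediator structures the
    report simply records the — possibly nonzero — gaps.
    """
    oracle = enumerate_oracle(model)
    report: dict = {"mediator_structure": model.mediator_structure, "gaps": {}}
    for k in model.mediators:
        gap_mech = abs(oracle.p_interventional[k] - oracle.p_mechanistic[k])
        gap_ident = abs(oracle.p_interventional[k] - oracle.p_identification[k])
        report["gaps"][k] = {"mechanistic": gap_mech, "identification": gap_ident}
        if model.mediator_structure == "d_separated" and (
                gap_mech > tol or gap_ident > tol):
            raise ContractError(
                f"identification equivalence violated for mediator {k!r}: "
                f"|interventional - mechanistic| = {gap_mech:.3g}, "
                f"|interventional - identification| = {gap_ident:.3g}"
            )
    report["equivalent"] = all(
        g["mechanistic"] <= tol and g["identification"] <= tol
        for g in report["gaps"].values()
    )
    return report


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def simulate_cohort(model: StructuralModel, n: int, seed: int = 0) -> StudyDataset:
    """n i.i.d. draws from the observational distribution, as a cohort."""
    if n <= 0:
        raise DegenerateDataError("cannot simulate an empty dataset (n must be >= 1)")
    rng = default_rng(seed)
    noise = _sample_noise(model, n, rng)
    world = _evaluate(model, noise, {}, n)
    df = pd.DataFrame({nd.name: world[nd.name] for nd in model.nodes})
    return StudyDataset(
        df=df, outcome=model.outcome, exposure=model.exposure,
        covariates=model.covariates, mediator_specs=model.mediator_specs(),
        design=StudyDesign("cohort"),
    )


def _true_prevalence(model: StructuralModel, seed: int) -> float:
    if model.true_prevalence is not None:
        return model.true_prevalence
    if model.all_discrete:
        return enumerate_oracle(model).p_y
    return mc_oracle(model, n_draws=1_000_000, seed=seed).p_y


def sample_case_control(model: StructuralModel, n_cases: int, r: float = 1.0,
                        seed: int = 0,
                        prevalence: float | None = None) -> StudyDataset:
    """1:r case-control sample: cases drawn from the law given Y=1, controls
    given Y=0 (rejection sampling from the observational distribution).

    The attached design carries the model's true disease prevalence so that
    :func:`pspaf.data.compute_weights` reconstructs the source population.
    """
    if n_cases <= 0 or r < 1:
        raise ConfigurationError("need n_cases >= 1 and r >= 1")
    rng = default_rng(seed)
    pi = prevalence if prevalence is not None else _true_prevalence(model, seed + 1)
    n_controls = int(round(r * n_cases))
    cases, controls = [], []
    got_cases = got_controls = 0
    batch = max(int(1.5 * n_cases / max(pi, 1e-6)), 10_000)
    batch = min(batch, 2_000_000)
    while got_cases < n_cases or got_controls < n_controls:
        noise = _sample_noise(model, batch, rng)
        world = _evaluate(model, noise, {}, batch)
        df = pd.DataFrame({nd.name: world[nd.name] for nd in model.nodes})
        y = df[model.outcome].to_numpy()
        if got_cases < n_cases:
            cases.append(df[y == 1].iloc[: n_cases - got_cases])
            got_cases += len(cases[-1])
        if got_controls < n_controls:
            controls.append(df[y == 0].iloc[: n_controls - got_controls])
            got_controls += len(controls[-1])
    df = pd.concat(cases + controls, ignore_index=True)
    # shuffle so record order carries no design information
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return StudyDataset(
        df=df, outcome=model.outcome, exposure=model.exposure,
        covariates=model.covariates, mediator_specs=model.mediator_specs(),
        design=StudyDesign("case_control", prevalence=pi, matching_ratio=r),
    )


# ---------------------------------------------------------------------------
# canonical models
# ---------------------------------------------------------------------------

def toy1() -> StructuralModel:
    """Canonical three-parameter Bernoulli model used throughout the tests.

    A ~ Bern(0.5); M | A ~ Bern(0.2 + 0.6 A); Y | A, M ~ Bern(0.1 + 0.3 A + 0.4 M).
    Exact functionals: P(Y=1) = 0.45, total PAF = 0.6, PS-PAF = 4/15,
    direct PAF = 1/3, indirect PAF = 4/15.
    """
    a = bernoulli_node("A", (), lambda v: 0.5)
    m = bernoulli_node("M", ("A",), lambda v: 0.2 + 0.6 * v["A"])
    y = bernoulli_node("Y", ("A", "M"),
                       lambda v: 0.1 + 0.3 * v["A"] + 0.4 * v["M"])
    return StructuralModel(nodes=(a, m, y), covariates=(), exposure="A",
                           mediators=("M",), outcome="Y", name="toy1")


def two_mediator_toy() -> StructuralModel:
    """Two d-separated binary mediators with a binary covariate."""
    c = bernoulli_node("C", (), lambda v: 0.3)
    a = bernoulli_node("A", ("C",), lambda v: 0.4 + 0.2 * v["C"])
    m1 = bernoulli_node("M1", ("A", "C"),
                        lambda v: 0.2 + 0.4 * v["A"] + 0.1 * v["C"])
    m2 = bernoulli_node("M2", ("A", "C"),
                        lambda v: 0.1 + 0.3 * v["A"] + 0.2 * v["C"])
    y = bernoulli_node(
        "Y", ("A", "M1", "M2", "C"),
        lambda v: 0.05 + 0.15 * v["A"] + 0.2 * v["M1"] + 0.25 * v["M2"]
        + 0.05 * v["C"])
    return StructuralModel(nodes=(c, a, m1, m2, y), covariates=("C",),
                           exposure="A", mediators=("M1", "M2"), outcome="Y",
                           name="toy2")


def random_logistic_sem(rng, n_mediators: int = 2, with_covariate: bool = True,
                        monotone: bool = True) -> StructuralModel:
    """Random logistic SEM with d-separated binary mediators.

    With ``monotone=True`` every structural effect of the exposure and of the
    mediators is risk-increasing (monotone-deleterious); otherwise those
    effects may take either sign.
    """
    nodes = []
    covariates: tuple[str, ...] = ()
    if with_covariate:
        pc = rng.uniform(0.2, 0.8)
        nodes.append(bernoulli_node("C", (), lambda v, pc=pc: pc))
        covariates = ("C",)
    a0 = rng.uniform(-1.0, 1.0)
    ac = rng.uniform(-1.0, 1.0) if with_covariate else 0.0
    parents_a = ("C",) if with_covariate else ()
    nodes.append(bernoulli_node(
        "A", parents_a,
        lambda v, a0=a0, ac=ac: expit(a0 + (ac * v["C"] if "C" in v else 0.0))))
    lo, hi = (0.3, 2.0) if monotone else (-2.0, 2.0)
    mediators = []
    med_effects = []
    for j in range(n_mediators):
        name = f"M{j + 1}"
        b0 = rng.uniform(-1.5, 0.0)
        ba = rng.uniform(lo, hi)        # A -> M (risk-increasing if monotone)
        bc = rng.uniform(-1.0, 1.0) if with_covariate else 0.0
        parents = ("A", "C") if with_covariate else ("A",)
        nodes.append(bernoulli_node(
            name, parents,
            lambda v, b0=b0, ba=ba, bc=bc: expit(
                b0 + ba * v["A"] + (bc * v["C"] if "C" in v else 0.0))))
        mediators.append(name)
        med_effects.append(rng.uniform(lo, hi))    # M -> Y
    g0 = rng.uniform(-3.0, -1.0)
    ga = rng.uniform(lo if monotone else -1.5, 1.5)  # A -> Y
    gc = rng.uniform(-1.0, 1.0) if with_covariate else 0.0
    parents_y = ("A", *mediators) + (("C",) if with_covariate else ())

    def py(v, g0=g0, ga=ga, gc=gc, med_effects=tuple(med_effects),
           mediators=tuple(mediators)):
        eta = g0 + ga * v["A"]
        for name, gm in zip(mediators, med_effects):
            eta = eta + gm * v[name]
        if "C" in v:
            eta = eta + gc * v["C"]
        return expit(eta)

    nodes.append(bernoulli_node("Y", parents_y, py))
    return StructuralModel(nodes=tuple(nodes), covariates=covariates,
                           exposure="A", mediators=tuple(mediators),
                           outcome="Y",
                           name="random_monotone" if monotone else "random_logistic")


def random_monotone_sem(rng, n_mediators: int = 2,
                        with_covariate: bool = True) -> StructuralModel:
    """Random monotone-deleterious SEM on the additive-risk scale.

    All structural effects of the exposure and mediators are risk-increasing
    and the direct and mediated pathways act synergistically (nonnegative
    exposure-mediator interaction in the outcome's risk).  In this class the
    pathway-specific PAF dominates the indirect PAF and the total PAF
    dominates every pathway-specific PAF — the ordering that holds when
    direct and mediated mechanisms must both be operational to cause disease.
    Parameters are drawn so that no probability needs clipping.
    """
    nodes = []
    covariates: tuple[str, ...] = ()
    if with_covariate:
        pc = rng.uniform(0.2, 0.8)
        nodes.append(bernoulli_node("C", (), lambda v, pc=pc: pc))
        covariates = ("C",)
    a0 = rng.uniform(0.2, 0.6)
    ac = rng.uniform(0.0, 0.3) if with_covariate else 0.0
    parents_a = ("C",) if with_covariate else ()
    nodes.append(bernoulli_node(
        "A", parents_a,
        lambda v, a0=a0, ac=ac: a0 + (ac * v["C"] if "C" in v else 0.0)))
    mediators = []
    for j in range(n_mediators):
        name = f"M{j + 1}"
        b0 = rng.uniform(0.05, 0.3)
        ba = rng.uniform(0.1, 0.5)       # risk-increasing A -> M
        bc = rng.uniform(0.0, 0.15) if with_covariate else 0.0
        parents = ("A", "C") if with_covariate else ("A",)
        nodes.append(bernoulli_node(
            name, parents,
            lambda v, b0=b0, ba=ba, bc=bc: b0 + ba * v["A"]
            + (bc * v["C"] if "C" in v else 0.0)))
        mediators.append(name)
    g0 = rng.uniform(0.02, 0.1)
    # positive main effects, mediator effects, exposure-mediator synergies
    # and covariate effect, rescaled so the maximal risk stays below 0.9
    raw = rng.uniform(0.05, 1.0, size=2 * n_mediators + 2)
    raw *= rng.uniform(0.3, 0.85 - g0) / raw.sum()
    ga, gc = raw[0], (raw[1] if with_covariate else 0.0)
    gm = raw[2:2 + n_mediators]
    synergy = raw[2 + n_mediators:]
    parents_y = ("A", *mediators) + (("C",) if with_covariate else ())

    def py(v, g0=g0, ga=ga, gc=gc, gm=tuple(gm), synergy=tuple(synergy),
           mediators=tuple(mediators)):
        p = g0 + ga * v["A"]
        for name, g, d in zip(mediators, gm, synergy):
            p = p + g * v[name] + d * v["A"] * v[name]
        if "C" in v:
            p = p + gc * v["C"]
        return p

    nodes.append(bernoulli_node("Y", parents_y, py))
    return StructuralModel(nodes=tuple(nodes), covariates=covariates,
                           exposure="A", mediators=tuple(mediators),
                           outcome="Y", name="random_monotone")


# ---------------------------------------------------------------------------
# synthetic stroke-study generator
# ---------------------------------------------------------------------------

_STROKE_COEFS = {
    "phys": 0.45, "hbp": 0.6, "whr": 3.0, "apob": 0.5,
    "age": 0.045, "sex": 0.2, "smoke": 0.35, "stress": 0.25,
    "alcoh": 0.15, "diet": -0.15,
}


def _build_stroke_model(alpha: float, exposure_effect: float = 1.0) -> StructuralModel:
    """Stroke-study structural model; ``exposure_effect`` scales every
    structural effect of physical inactivity (0 gives the global null)."""
    e = exposure_effect
    nodes = [
        GaussianNode("age", (), lambda v, n: np.full(n, 55.0), sd=10.0),
        bernoulli_node("sex", (), lambda v: 0.5),
        DiscreteNode("region", (0, 1, 2), (),
                     lambda v, n: np.broadcast_to([0.4, 0.35, 0.25], (n, 3))),
        DiscreteNode("educ", (0, 1, 2), (),
                     lambda v, n: np.broadcast_to([0.3, 0.4, 0.3], (n, 3))),
        GaussianNode("diet", (), lambda v, n: np.zeros(n), sd=1.0),
        bernoulli_node("stress", (), lambda v: 0.2),
        bernoulli_node("smoke", (), lambda v: 0.25),
        bernoulli_node("alcoh", (), lambda v: 0.3),
        bernoulli_node(
            "phys", ("age", "sex", "region", "educ"),
            lambda v: expit(-1.0 + 0.012 * (v["age"] - 55.0) + 0.15 * v["sex"]
                            + 0.1 * (v["region"] == 1) - 0.15 * (v["educ"] == 2))),
        bernoulli_node(
            "hbp", ("phys", "age", "stress", "alcoh", "sex"),
            lambda v: expit(-1.2 + e * 0.5 * v["phys"] + 0.04 * (v["age"] - 55.0)
                            + 0.3 * v["stress"] + 0.2 * v["alcoh"]
                            + 0.1 * v["sex"])),
        GaussianNode(
            "whr", ("phys", "age", "sex", "diet"),
            lambda v, n: (0.85 + e * 0.04 * v["phys"] + 0.002 * (v["age"] - 55.0)
                          + 0.03 * v["sex"] - 0.01 * v["diet"]),
            sd=0.06),
        GaussianNode(
            "apob", ("phys", "smoke", "diet", "age"),
            lambda v, n: (0.9 + e * 0.08 * v["phys"] + 0.05 * v["smoke"]
                          - 0.03 * v["diet"] + 0.002 * (v["age"] - 55.0)),
            sd=0.25),
        bernoulli_node(
            "stroke",
            ("phys", "hbp", "whr", "apob", "age", "sex", "smoke", "stress",
             "alcoh", "diet"),
            lambda v, alpha=alpha, e=e: expit(
                alpha
                + e * _STROKE_COEFS["phys"] * v["phys"]
                + _STROKE_COEFS["hbp"] * v["hbp"]
                + _STROKE_COEFS["whr"] * (v["whr"] - 0.85)
                + _STROKE_COEFS["apob"] * (v["apob"] - 0.9)
                + _STROKE_COEFS["age"] * (v["age"] - 55.0)
                + _STROKE_COEFS["sex"] * v["sex"]
                + _STROKE_COEFS["smoke"] * v["smoke"]
                + _STROKE_COEFS["stress"] * v["stress"]
                + _STROKE_COEFS["alcoh"] * v["alcoh"]
                + _STROKE_COEFS["diet"] * v["diet"])),
    ]
    return StructuralModel(
        nodes=tuple(nodes),
        covariates=("age", "sex", "region", "educ", "diet", "stress",
                    "smoke", "alcoh"),
        exposure="phys", mediators=("hbp", "whr", "apob"), outcome="stroke",
        name="stroke_synthetic",
    )


_CALIBRATION_SEED = 20220510  # internal; makes the calibrated model deterministic
_calibration_cache: dict[tuple, float] = {}


def _calibrate_stroke_intercept(target: float, exposure_effect: float) -> float:
    """Choose the outcome intercept so the marginal incidence hits ``target``.

    Root-finds on the mean outcome probability over a fixed 400k Monte-Carlo
    sample of the linear predictor (internal fixed seed, so the returned
    model does not depend on the caller's seed).
    """
    key = (round(target, 12), round(exposure_effect, 12))
    if key in _calibration_cache:
        return _calibration_cache[key]
    probe = _build_stroke_model(alpha=0.0, exposure_effect=exposure_effect)
    n = 400_000
    rng = default_rng(_CALIBRATION_SEED)
    noise = _sample_noise(probe, n, rng)
    world = _evaluate(probe, noise, {}, n, skip_outcome=True)
    ynode = probe.node(probe.outcome)
    parent_vals = {p: world[p] for p in ynode.parents}
    # linear predictor at alpha = 0
    p0 = np.clip(ynode.prob_fn(parent_vals, n)[:, 1], 1e-300, 1 - 1e-16)
    lp = np.log(p0 / (1.0 - p0))
    alpha = brentq(lambda a: expit(a + lp).mean() - target, -20.0, 5.0, xtol=1e-10)
    _calibration_cache[key] = alpha
    return alpha


def make_interstroke_like(seed: int = 0, n: int | None = None,
                          n_cases: int | None = None, r: float = 1.0,
                          target_incidence: float = 0.0035,
                          exposure_effect: float = 1.0
                          ) -> tuple[StudyDataset, StructuralModel]:
    """Synthetic stroke case-control study generator.

    Emulates the structure of a large international stroke case-control
    study: baseline confounders (age, sex, region, education, diet score,
    stress, smoking, alcohol), a binary physical-inactivity exposure, a
    binary hypertension mediator, continuous waist-hip-ratio and
    ApoB/ApoA-ratio mediators (Gaussian given exposure and covariates), and a
    rare stroke outcome with marginal incidence calibrated to
    ``target_incidence`` (default 3.5 per 1000).  Returns the dataset (a 1:r
    case-control sample by default, or a cohort when ``n`` is given) together
    with the structural model, whose functionals are available through
    :func:`mc_oracle`.
    """
    alpha = _calibrate_stroke_intercept(target_incidence, exposure_effect)
    model = _build_stroke_model(alpha=alpha, exposure_effect=exposure_effect)
    model.true_prevalence = target_incidence
    if n is not None:
        ds = simulate_cohort(model, n, seed)
    else:
        if n_cases is None:
            n_cases = 1000
        ds = sample_case_control(model, n_cases=n_cases, r=r, seed=seed,
                                 prevalence=target_incidence)
    return ds, model


# ---------------------------------------------------------------------------
# (de)serialization of discrete models
# ---------------------------------------------------------------------------

def model_to_dict(model: StructuralModel) -> dict:
    """Serializable description of an all-discrete model (CPT tables)."""
    if not model.all_discrete:
        raise UnsupportedStructureError(
            "only all-discrete models can be serialized to CPT tables"
        )
    supports = {nd.name: tuple(nd.levels) for nd in model.nodes}
    nodes = []
    for nd in model.nodes:
        table = []
        for cfg in itertools.product(*[supports[p] for p in nd.parents]):
            vals = {p: np.asarray([v]) for p, v in zip(nd.parents, cfg)}
            probs = nd.prob_fn(vals, 1)[0]
            table.append({"given": list(cfg),
                          "probs": [float(p) for p in probs]})
        nodes.append({"name": nd.name, "levels": list(nd.levels),
                      "parents": list(nd.parents), "table": table})
    return {
        "name": model.name,
        "nodes": nodes,
        "covariates": list(model.covariates),
        "exposure": model.exposure,
        "mediators": list(model.mediators),
        "outcome": model.outcome,
        "mediator_structure": model.mediator_structure,
    }


def model_from_dict(d: Mapping) -> StructuralModel:
    """Rebuild a discrete model from :func:`model_to_dict` output."""
    level_map = {nd["name"]: [_coerce(v) for v in nd["levels"]] for nd in d["nodes"]}
    nodes = []
    for nd in d["nodes"]:
        parents = tuple(nd["parents"])
        table = {tuple(_coerce(v) for v in row["given"]): row["probs"]
                 for row in nd["table"]}
        nodes.append(tabular_node(nd["name"], level_map[nd["name"]], parents,
                                  [level_map[p] for p in parents], table))
    return StructuralModel(
        nodes=tuple(nodes), covariates=tuple(d.get("covariates", ())),
        exposure=d["exposure"], mediators=tuple(d["mediators"]),
        outcome=d["outcome"],
        mediator_structure=d.get("mediator_structure", "d_separated"),
        name=d.get("name"),
    )


def _coerce(v):
    """YAML round-trips numeric levels as int/float already; pass through."""
    return v
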