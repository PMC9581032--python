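"""Growth-coupled reaction-deletion design by dynamic solution-space division.

This module implements three related strain-design searches over
constraint-based metabolic models:

* **GridProd** — grids the (growth rate, production rate) plane into P x P
  cells and, in each cell, minimizes total flux to propose a knockout set.
* **CubeProd** — adds the total-absolute-flux axis (SF) and searches the
  P x P x P cubes of the (GR, PR, SF) box.
* **DynCubeProd** — starts from a single cube and repeatedly doubles the
  number of divisions per axis, skipping every child of a cube whose
  candidate LP was infeasible at the coarser level (infeasibility of a
  region is inherited by its subsets), and stopping at the first knockout
  set that validates as growth-coupled.

A knockout set K is *accepted* when, after forcing the fluxes of K to zero,
maximizing growth yields GR >= min_growth and the minimum production rate at
that maximal growth is PR >= min_target: the target metabolite is then a
mandatory by-product of optimal growth.

The module is organised in the order the method runs: configuration and
errors, model types and I/O, the LP layer, the subdivision search, and the
command back-ends used by the CLI in :mod:`dyncubeprod.__main__`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import linprog

__all__ = [
    # model_io
    "MetabolicModel",
    "MediumCondition",
    "read_model",
    "write_model",
    "apply_medium",
    "add_target_exchange",
    "build_toy_network",
    "generate_random_network",
    # lp_core
    "FluxDistribution",
    "TheoreticalMaxima",
    "BoxConstraint",
    "solve_fba",
    "compute_theoretical_maxima",
    "min_total_flux",
    "validate_deletion",
    "extract_candidate",
    "default_protected",
    # division
    "Cube",
    "FeasibilityGrid",
    "SearchParams",
    "DeletionStrategy",
    "CubeRecord",
    "SearchResult",
    "cube_bounds",
    "refine_mask",
    "examine_cube",
    "run_dyncubeprod",
    "run_cubeprod",
    "run_gridprod",
    # cli back-end
    "RunConfig",
    "cmd_design",
    "cmd_batch",
    "cmd_fixture",
    "EXIT_ACCEPTED",
    "EXIT_USAGE",
    "EXIT_NO_STRATEGY",
    "EXIT_DATA",
    "EXIT_SOLVER",
    # errors
    "DynCubeProdError",
    "FormatError",
    "RoleError",
    "UnknownIdError",
    "ModelInfeasibleError",
    "SolverError",
    "GenerationError",
    "ContractError",
]

# --------------------------------------------------------------------------
# Configuration & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("dyncubeprod")

#: Flux threshold below which a reaction is considered inactive and becomes
#: part of a candidate knockout set (absolute value, strict inequality).
FLUX_EPSILON = 1e-5

#: Relative tolerance used when fixing growth at its stage-1 maximum in the
#: validation LP (exact equality is brittle in floating point).
GROWTH_FIX_RTOL = 1e-6

#: Tolerance for post-hoc feasibility checks (steady state, bounds).
CHECK_TOL = 1e-6

#: Upper bound given to auxiliary target-export reactions.
AUX_EXCHANGE_UB = 1000.0

#: Native JSON dialect tag.
_NATIVE_FORMAT = "dyncubeprod-model/1"

#: Default medium for iJO1366-style E. coli models (mmol gDW^-1 h^-1).
#: GUR = glucose uptake, OUR = oxygen uptake (0 = anaerobic), NGAM =
#: non-growth-associated ATP maintenance.
DEFAULT_GUR = 10.0
DEFAULT_OUR_AEROBIC = 1000.0
DEFAULT_NGAM = 3.15

_ROLE_KEYS = ("growth", "target", "glucose_uptake", "oxygen_uptake", "atp_maintenance")

# Exit codes of the CLI commands; disjoint by contract.
EXIT_ACCEPTED = 0
EXIT_USAGE = 2  # click's own usage-error code
EXIT_NO_STRATEGY = 3
EXIT_DATA = 4
EXIT_SOLVER = 5


class DynCubeProdError(Exception):
    """Base class for errors raised by this package."""


class FormatError(DynCubeProdError):
    """A model file could not be parsed under the named standard."""


class RoleError(DynCubeProdError):
    """A required special reaction (growth, target, ...) is missing."""


class UnknownIdError(DynCubeProdError, KeyError):
    """A metabolite or reaction identifier is not in the model."""


class ModelInfeasibleError(DynCubeProdError):
    """The base model admits no steady-state flux within bounds."""


class SolverError(DynCubeProdError):
    """The LP solver failed for a reason other than infeasibility."""


class GenerationError(DynCubeProdError):
    """The random-network generator exhausted its retries."""


class ContractError(DynCubeProdError, ValueError):
    """An operation was called outside its contract."""


# --------------------------------------------------------------------------
# model_io: model types, parsing, medium, fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumCondition:
    """Uptake/maintenance limits defining the growth medium.

    Attributes
    ----------
    gur : float
        Maximum glucose uptake rate (>= 0), applied as lower bound -GUR on
        the glucose exchange.
    our : float
        Maximum oxygen uptake rate (>= 0); 0 means anaerobic.
    ngam : float
        Minimum non-growth-associated ATP maintenance flux (>= 0), applied
        as a lower bound on the ATPM reaction.
    """

    gur: float
    our: float
    ngam: float = DEFAULT_NGAM

    def __post_init__(self) -> None:
        for name in ("gur", "our", "ngam"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ContractError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class MetabolicModel:
    """A constraint-based metabolic model: S, bounds, and reaction roles.

    ``S`` is the m x n stoichiometric matrix over the *internal* metabolites;
    boundary transport is represented by exchange reactions (columns with a
    single nonzero entry), whose negative flux direction is uptake.
    ``roles`` maps the special-reaction keys (``growth``, ``target``,
    ``glucose_uptake``, ``oxygen_uptake``, ``atp_maintenance``) to reaction
    identifiers; only the roles a model actually has are present.
    """

    metabolite_ids: tuple
    reaction_ids: tuple
    S: np.ndarray
    LB: np.ndarray
    UB: np.ndarray
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        S = np.asarray(self.S, dtype=float).reshape(m, n)
        LB = np.asarray(self.LB, dtype=float).reshape(n)
        UB = np.asarray(self.UB, dtype=float).reshape(n)
        for a in (S, LB, UB):
            a.setflags(write=False)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "LB", LB)
        object.__setattr__(self, "UB", UB)
        object.__setattr__(self, "roles", dict(self.roles))
        if len(set(self.reaction_ids)) != n:
            raise FormatError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise FormatError("duplicate metabolite identifiers")
        if np.any(LB > UB):
            j = int(np.argmax(LB > UB))
            raise FormatError(
                f"reaction {self.reaction_ids[j]!r}: LB {LB[j]} > UB {UB[j]}"
            )
        empty = np.where(~np.any(S != 0.0, axis=1))[0]
        if empty.size:
            raise FormatError(
                f"isolated metabolite(s): {[self.metabolite_ids[i] for i in empty]}"
            )
        for key, rid in self.roles.items():
            if key not in _ROLE_KEYS:
                raise RoleError(f"unknown role key {key!r}")
            if rid not in self.reaction_ids:
                raise RoleError(f"role {key!r} maps to unknown reaction {rid!r}")

    # -- indexing helpers ---------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise UnknownIdError(f"unknown reaction {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise UnknownIdError(f"unknown metabolite {mid!r}") from None

    def role_reaction(self, key: str) -> str:
        if key not in self.roles:
            raise RoleError(f"model has no {key!r} reaction")
        return self.roles[key]

    def exchange_reactions(self) -> tuple:
        """Reaction ids whose column has exactly one nonzero entry."""
        counts = np.count_nonzero(self.S, axis=0)
        return tuple(r for r, c in zip(self.reaction_ids, counts) if c == 1)

    # -- copy-on-write ------------------------------------------------------

    def with_bounds(self, overrides: Mapping[str, tuple]) -> "MetabolicModel":
        """Return a copy with per-reaction (lb, ub) bound overrides."""
        LB, UB = self.LB.copy(), self.UB.copy()
        for rid, (lo, hi) in overrides.items():
            j = self.reaction_index(rid)
            LB[j], UB[j] = lo, hi
        return dataclasses.replace(self, LB=LB, UB=UB)

    def with_roles(self, **roles: str) -> "MetabolicModel":
        merged = dict(self.roles)
        merged.update(roles)
        return dataclasses.replace(self, roles=merged)

    # -- native JSON dialect ------------------------------------------------

    def to_dict(self) -> dict:
        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            mets = {
                self.metabolite_ids[i]: float(col[i])
                for i in np.flatnonzero(col)
            }
            reactions.append(
                {
                    "id": rid,
                    "lb": float(self.LB[j]),
                    "ub": float(self.UB[j]),
                    "metabolites": mets,
                }
            )
        return {
            "format": _NATIVE_FORMAT,
            "metabolites": list(self.metabolite_ids),
            "reactions": reactions,
            "roles": dict(self.roles),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MetabolicModel":
        try:
            if data.get("format") != _NATIVE_FORMAT:
                raise FormatError(
                    f"not a {_NATIVE_FORMAT} document (format={data.get('format')!r})"
                )
            mids = list(data["metabolites"])
            rids = [r["id"] for r in data["reactions"]]
            S = np.zeros((len(mids), len(rids)))
            LB = np.zeros(len(rids))
            UB = np.zeros(len(rids))
            midx = {m: i for i, m in enumerate(mids)}
            for j, r in enumerate(data["reactions"]):
                LB[j], UB[j] = float(r["lb"]), float(r["ub"])
                for mid, coef in r["metabolites"].items():
                    S[midx[mid], j] = float(coef)
            return cls(tuple(mids), tuple(rids), S, LB, UB, dict(data.get("roles", {})))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed model document: {exc}") from exc


def write_model(model: MetabolicModel, path: str) -> None:
    """Serialize a model to the native JSON dialect (deterministic bytes)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# BiGG conventional identifiers used for role autodetection.
_BIGG_GLC = ("EX_glc__D_e", "EX_glc_e")
_BIGG_O2 = ("EX_o2_e",)
_BIGG_ATPM = ("ATPM",)


def _autodetect_roles(cobra_model) -> dict:
    roles = {}
    biomass = [
        r.id for r in cobra_model.reactions if r.objective_coefficient
    ] or [r.id for r in cobra_model.reactions if "biomass" in r.id.lower()]
    if biomass:
        roles["growth"] = biomass[0]
    ids = {r.id for r in cobra_model.reactions}
    for key, candidates in (
        ("glucose_uptake", _BIGG_GLC),
        ("oxygen_uptake", _BIGG_O2),
        ("atp_maintenance", _BIGG_ATPM),
    ):
        for rid in candidates:
            if rid in ids:
                roles[key] = rid
                break
    return roles


def _from_cobra(cobra_model, roles_override: Optional[Mapping[str, str]]) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cobra_model, array_type="dense")
    rids = tuple(r.id for r in cobra_model.reactions)
    mids = tuple(m.id for m in cobra_model.metabolites)
    LB = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    UB = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)
    # cobra may carry metabolites referenced by no reaction; drop them.
    used = np.any(S != 0.0, axis=1)
    if not used.all():
        S = S[used]
        mids = tuple(m for m, u in zip(mids, used) if u)
    roles = _autodetect_roles(cobra_model)
    if roles_override:
        roles.update(roles_override)
    return MetabolicModel(mids, rids, S, LB, UB, roles)


def read_model(
    path: str,
    format: Optional[str] = None,
    roles: Optional[Mapping[str, str]] = None,
) -> MetabolicModel:
    """Read a model from SBML (L3+FBC), BiGG JSON, or the native dialect.

    Parameters
    ----------
    path : str
        Model file path.
    format : {"sbml", "bigg_json", "native", None}
        File format; ``None`` autodetects from the extension (and, for
        ``.json``, from the document's ``format`` tag).
    roles : mapping, optional
        Role overrides (always win over autodetection).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        if ext in (".xml", ".sbml"):
            format = "sbml"
        elif ext == ".json":
            with open(path) as fh:
                head = fh.read(4096)
            format = "native" if _NATIVE_FORMAT in head else "bigg_json"
        else:
            raise FormatError(f"cannot infer model format from {path!r}")
    if format == "native":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        model = MetabolicModel.from_dict(data)
        return model.with_roles(**roles) if roles else model
    if format == "bigg_json":
        import cobra.io

        try:
            cb = cobra.io.load_json_model(path)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        except Exception as exc:  # cobra raises assorted types on bad schema
            raise FormatError(f"{path}: not a BiGG JSON model ({exc})") from exc
        return _from_cobra(cb, roles)
    if format == "sbml":
        import cobra.io

        try:
            cb = cobra.io.read_sbml_model(path)
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        return _from_cobra(cb, roles)
    raise ContractError(f"unknown format {format!r}")


def apply_medium(model: MetabolicModel, medium: MediumCondition) -> MetabolicModel:
    """Constrain the uptake/maintenance reactions to a medium condition.

    Sets the glucose-exchange lower bound to -GUR, the oxygen-exchange lower
    bound to -OUR and the ATP-maintenance lower bound to NGAM. Roles the
    model does not define are skipped with a warning. Idempotent.
    """
    overrides = {}
    for key, lo_of in (
        ("glucose_uptake", lambda m: -m.gur),
        ("oxygen_uptake", lambda m: -m.our),
        ("atp_maintenance", lambda m: m.ngam),
    ):
        if key not in model.roles:
            logger.warning("apply_medium: model has no %s role; skipped", key)
            continue
        j = model.reaction_index(model.roles[key])
        overrides[model.roles[key]] = (lo_of(medium), float(model.UB[j]))
    return model.with_bounds(overrides) if overrides else model


def add_target_exchange(model: MetabolicModel, metabolite: str) -> MetabolicModel:
    """Designate (or create) an export reaction for a target metabolite.

    If the metabolite already feeds an irreversible export (an exchange
    column whose only entry is negative, with positive capacity), that
    reaction becomes the ``target`` role and the model is otherwise
    unchanged.  Otherwise an auxiliary export column (single entry -1,
    bounds [0, 1000]) is appended and made the target.
    """
    i = model.metabolite_index(metabolite)
    counts = np.count_nonzero(model.S, axis=0)
    for j in np.flatnonzero(counts == 1):
        if model.S[i, j] < 0 and model.UB[j] > 0:
            return model.with_roles(target=model.reaction_ids[j])
    rid = f"EX_{metabolite}_target"
    if rid in model.reaction_ids:  # pragma: no cover - defensive
        raise FormatError(f"auxiliary reaction id {rid!r} already exists")
    col = np.zeros((model.n_metabolites, 1))
    col[i, 0] = -1.0
    return MetabolicModel(
        model.metabolite_ids,
        model.reaction_ids + (rid,),
        np.hstack([model.S, col]),
        np.append(model.LB, 0.0),
        np.append(model.UB, AUX_EXCHANGE_UB),
        {**model.roles, "target": rid},
    )


# Frozen transcription of the 7-reaction / 4-metabolite toy network:
#   R1 fixed nutrient input to C1; R2/R4 the C1->C2->C3 route; R3 the direct
#   C1->C4 route to the growth precursor; R5 the capacity-limited (<=1)
#   C3->C4 route; R6 growth export of C4; R7 target export of C3.
_TOY = {
    "format": _NATIVE_FORMAT,
    "metabolites": ["C1", "C2", "C3", "C4"],
    "reactions": [
        {"id": "R1", "lb": 3.0, "ub": 3.0, "metabolites": {"C1": 1.0}},
        {"id": "R2", "lb": 0.0, "ub": 10.0, "metabolites": {"C1": -1.0, "C2": 1.0}},
        {"id": "R3", "lb": 0.0, "ub": 10.0, "metabolites": {"C1": -1.0, "C4": 1.0}},
        {"id": "R4", "lb": 0.0, "ub": 10.0, "metabolites": {"C2": -1.0, "C3": 1.0}},
        {"id": "R5", "lb": 0.0, "ub": 1.0, "metabolites": {"C3": -1.0, "C4": 1.0}},
        {"id": "R6", "lb": 0.0, "ub": 10.0, "metabolites": {"C4": -1.0}},
        {"id": "R7", "lb": 0.0, "ub": 10.0, "metabolites": {"C3": -1.0}},
    ],
    "roles": {"growth": "R6", "target": "R7"},
}


def build_toy_network() -> MetabolicModel:
    """The 7-reaction / 4-internal-metabolite example network.

    A fixed nutrient influx of 3 enters C1 and is split between a direct
    route to the growth precursor C4 (R3) and a two-step route to C3
    (R2, R4), from which a capacity-limited reaction (R5, flux <= 1) also
    feeds C4. R6 exports C4 (growth), R7 exports C3 (target product).
    Deleting R3 forces production: growth is then capped at 1 by R5 while
    the remaining influx must leave through the target export.
    """
    return MetabolicModel.from_dict(_TOY)


def generate_random_network(
    n_metabolites: int,
    n_reactions: int,
    seed: int,
    max_retries: int = 20,
) -> MetabolicModel:
    """Generate a random mass-balanced, fully irreversible test network.

    The network carries a fixed integer nutrient influx u (2..5) into M1,
    a backbone chain M1 -> M2 -> ... -> Mm (capacity 10 >= u, so a nonzero
    growth flux is always feasible), a growth export from Mm, a target
    export from a random metabolite, and random cross-edges, some with
    tight capacities that create toy-R5-style bottlenecks.  All bounds are
    integer-valued, so exact rational oracles apply.  Deterministic in
    ``seed``.
    """
    if n_reactions < n_metabolites + 2:
        raise ContractError("need n_reactions >= n_metabolites + 2")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        m = n_metabolites
        mids = [f"M{i + 1}" for i in range(m)]
        u = int(rng.integers(2, 6))
        cols = []  # (rid, {mid: coef}, lb, ub)
        cols.append((f"R_uptake", {mids[0]: 1.0}, float(u), float(u)))
        for i in range(m - 1):  # backbone chain: every metabolite produced+consumed
            cols.append((f"R_chain{i + 1}", {mids[i]: -1.0, mids[i + 1]: 1.0}, 0.0, 10.0))
        n_extra = n_reactions - 2 - (m - 1) - 1
        for e in range(n_extra):
            a, b = rng.choice(m, size=2, replace=False)
            cap = float(rng.integers(1, u + 1)) if rng.random() < 0.4 else 10.0
            cols.append((f"R_branch{e + 1}", {mids[a]: -1.0, mids[b]: 1.0}, 0.0, cap))
        t = int(rng.integers(0, m))
        cols.append(("R_growth", {mids[m - 1]: -1.0}, 0.0, 10.0))
        cols.append(("R_target", {mids[t]: -1.0}, 0.0, 10.0))
        S = np.zeros((m, len(cols)))
        midx = {mid: i for i, mid in enumerate(mids)}
        for j, (_, mets, _, _) in enumerate(cols):
            for mid, coef in mets.items():
                S[midx[mid], j] = coef
        model = MetabolicModel(
            tuple(mids),
            tuple(c[0] for c in cols),
            S,
            np.array([c[2] for c in cols]),
            np.array([c[3] for c in cols]),
            {"growth": "R_growth", "target": "R_target"},
        )
        fba = solve_fba(model, "R_growth", "max")
        if fba.status == "optimal" and fba.objective > CHECK_TOL:
            return model
        logger.debug("generator retry %d for seed %s", attempt + 1, seed)
    raise GenerationError(
        f"no feasible network with nonzero growth after {max_retries} tries (seed={seed})"
    )


# --------------------------------------------------------------------------
# lp_core: FBA, theoretical maxima, first LP, validation LP
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxDistribution:
    """One LP outcome: solver status and, when optimal, the flux vector."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    reaction_ids: tuple = ()
    x: Optional[np.ndarray] = None
    objective: Optional[float] = None
    total_abs_flux: Optional[float] = None

    def flux(self, rid: str) -> float:
        if self.x is None:
            raise ContractError(f"no flux vector (status={self.status})")
        try:
            return float(self.x[self.reaction_ids.index(rid)])
        except ValueError:
            raise UnknownIdError(f"unknown reaction {rid!r}") from None

    def as_dict(self) -> dict:
        return {} if self.x is None else {
            r: float(v) for r, v in zip(self.reaction_ids, self.x)
        }


@dataclass(frozen=True)
class TheoreticalMaxima:
    """Axis limits of the (GR, PR, SF) solution space."""

    tmgr: float
    tmpr: float
    tmsf: float

    def __post_init__(self) -> None:
        if min(self.tmgr, self.tmpr, self.tmsf) < 0:
            raise ContractError("theoretical maxima must be non-negative")


@dataclass(frozen=True)
class BoxConstraint:
    """Closed interval constraints on growth (gr), production (pr) and
    total absolute flux (sf).  ``sf`` may be (0, inf) for grid searches."""

    gr: tuple
    pr: tuple
    sf: tuple

    def __post_init__(self) -> None:
        for name in ("gr", "pr", "sf"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ContractError(f"{name} interval must satisfy 0 <= lo <= hi")


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve_split_lp(
    model: MetabolicModel,
    *,
    c_reaction: Optional[Mapping[str, float]] = None,
    c_components: float = 0.0,
    sense: str = "min",
    extra_bounds: Optional[Mapping[str, tuple]] = None,
    sf_interval: Optional[tuple] = None,
) -> FluxDistribution:
    """Solve one LP over the split flux variables.

    Each reaction j contributes a forward component f_j and, when its lower
    bound is negative, a backward component b_j, with x_j = f_j - b_j.  The
    component sum Sum(f + b) is the LP-expressible surrogate for the total
    absolute flux Sum|x|, exact for irreversible models.  The objective is
    ``sense`` applied to  Sum_j c_reaction[j] * x_j + c_components * Sum(f+b).
    """
    n = model.n_reactions
    LB, UB = model.LB.copy(), model.UB.copy()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            LB[j], UB[j] = lo, hi
            if lo > hi:
                return FluxDistribution("infeasible", model.reaction_ids)
    # variable layout: [f_0..f_{n-1}, b for each reversible reaction]
    rev = np.flatnonzero(LB < 0)
    nb = rev.size
    f_lo, f_hi = np.maximum(LB, 0.0), np.maximum(UB, 0.0)
    b_lo, b_hi = np.maximum(-UB[rev], 0.0), np.maximum(-LB[rev], 0.0)
    bounds = list(zip(f_lo, f_hi)) + list(zip(b_lo, b_hi))
    A_eq = np.hstack([model.S, -model.S[:, rev]]) if nb else model.S
    b_eq = np.zeros(model.n_metabolites)
    c = np.full(n + nb, c_components, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    if c_reaction:
        for rid, coef in c_reaction.items():
            j = model.reaction_index(rid)
            c[j] += coef
            where = np.flatnonzero(rev == j)
            if where.size:
                c[n + where[0]] -= coef
    A_ub = b_ub = None
    if sf_interval is not None:
        lo, hi = sf_interval
        rows, rhs = [], []
        if math.isfinite(hi):
            rows.append(np.ones(n + nb))
            rhs.append(hi)
        if lo > 0:
            rows.append(-np.ones(n + nb))
            rhs.append(-lo)
        if rows:
            A_ub, b_ub = np.array(rows), np.array(rhs)
    res = linprog(
        sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=bounds, method="highs",
    )
    status = _LP_STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failure: {res.message}")
    if status != "optimal":
        return FluxDistribution(status, model.reaction_ids)
    z = np.asarray(res.x)
    x = z[:n].copy()
    x[rev] -= z[n:]
    resid = float(np.max(np.abs(model.S @ x))) if n else 0.0
    if resid > CHECK_TOL:  # pragma: no cover - solver contract
        raise SolverError(f"steady-state residual {resid} exceeds tolerance")
    return FluxDistribution(
        "optimal",
        model.reaction_ids,
        x,
        float(sign * res.fun),
        float(np.abs(x).sum()),
    )


def solve_fba(
    model: MetabolicModel,
    objective: str,
    sense: str = "max",
    extra_bounds: Optional[Mapping[str, tuple]] = None,
) -> FluxDistribution:
    """Plain FBA: optimize one reaction's flux at steady state within bounds."""
    model.reaction_index(objective)
    if sense not in ("max", "min"):
        raise ContractError(f"sense must be 'max' or 'min', got {sense!r}")
    return _solve_split_lp(
        model, c_reaction={objective: 1.0}, sense=sense, extra_bounds=extra_bounds
    )


def compute_theoretical_maxima(
    model: MetabolicModel, min_growth: float
) -> TheoreticalMaxima:
    """Compute the (TMGR, TMPR, TMSF) axis limits of the solution space.

    TMGR and TMPR are the unconstrained maxima of the growth and target
    fluxes.  TMSF is deterministic by construction: maximize production
    under growth >= min_growth, fix production at that optimum, and
    maximize the split-component flux sum over the optimal face (for
    irreversible models this is the largest total absolute flux compatible
    with growth-coupled maximal production).  If growth >= min_growth is
    itself infeasible, TMSF is 0.
    """
    growth = model.role_reaction("growth")
    target = model.role_reaction("target")
    gmax = solve_fba(model, growth, "max")
    if gmax.status == "infeasible":
        raise ModelInfeasibleError("base model admits no steady-state flux")
    if gmax.status != "optimal":
        raise SolverError(f"growth maximization {gmax.status}")
    tmgr = max(0.0, gmax.objective)
    pmax = solve_fba(model, target, "max")
    if pmax.status != "optimal":
        raise SolverError(f"target maximization {pmax.status}")
    tmpr = max(0.0, pmax.objective)
    jg = model.reaction_index(growth)
    g_lo = max(model.LB[jg], min_growth)
    pr_lp = solve_fba(model, target, "max", extra_bounds={growth: (g_lo, model.UB[jg])})
    if pr_lp.status == "infeasible":
        logger.warning(
            "growth >= %g infeasible (TMGR=%g); TMSF set to 0", min_growth, tmgr
        )
        return TheoreticalMaxima(tmgr, tmpr, 0.0)
    if pr_lp.status != "optimal":
        raise SolverError(f"constrained target maximization {pr_lp.status}")
    pr_star = pr_lp.objective
    jt = model.reaction_index(target)
    fix_lo = pr_star - 1e-9 * max(1.0, abs(pr_star))
    face = _solve_split_lp(
        model,
        c_components=1.0,
        sense="max",
        extra_bounds={
            growth: (g_lo, model.UB[jg]),
            target: (max(model.LB[jt], fix_lo), model.UB[jt]),
        },
    )
    if face.status != "optimal":
        raise SolverError(f"TMSF face maximization {face.status}")
    return TheoreticalMaxima(tmgr, tmpr, max(0.0, face.objective))


def min_total_flux(model: MetabolicModel, box: BoxConstraint) -> FluxDistribution:
    """The "first LP": minimize total absolute flux inside a (GR, PR, SF) box.

    Growth and production intervals intersect the native bounds; the SF
    interval is enforced on the split-component sum (exact for irreversible
    models).  Returns an infeasible distribution when the box misses the
    flux polytope.
    """
    growth = model.role_reaction("growth")
    target = model.role_reaction("target")
    jg, jt = model.reaction_index(growth), model.reaction_index(target)
    extra = {
        growth: (max(model.LB[jg], box.gr[0]), min(model.UB[jg], box.gr[1])),
        target: (max(model.LB[jt], box.pr[0]), min(model.UB[jt], box.pr[1])),
    }
    return _solve_split_lp(
        model, c_components=1.0, sense="min", extra_bounds=extra, sf_interval=box.sf
    )


def validate_deletion(model: MetabolicModel, K: Iterable[str]) -> tuple:
    """The "second LP": two-stage validation of a knockout set.

    Stage 1 maximizes growth with every reaction in K forced to zero (no box
    constraints).  Stage 2 minimizes production with growth additionally
    held at its stage-1 maximum (within a relative tolerance).  Returns
    ``(GRmax, PRmin)``; an infeasible stage collapses to the degenerate
    pair ``(0, 0)`` (never acceptable), with a logged flag.
    """
    K = frozenset(K)
    target = model.role_reaction("target")
    growth = model.role_reaction("growth")
    for rid in K:
        model.reaction_index(rid)
    if target in K:
        raise ContractError("the target reaction must not be deleted")
    knock = {rid: (0.0, 0.0) for rid in K}
    stage1 = solve_fba(model, growth, "max", extra_bounds=knock)
    if stage1.status != "optimal":
        logger.info("validation stage 1 %s for K=%s", stage1.status, sorted(K))
        return (0.0, 0.0)
    grmax = stage1.objective + 0.0  # normalize -0.0
    jg = model.reaction_index(growth)
    g_lo = grmax - GROWTH_FIX_RTOL * max(1.0, abs(grmax))
    stage2 = solve_fba(
        model,
        target,
        "min",
        extra_bounds={**knock, growth: (max(model.LB[jg], g_lo), model.UB[jg])},
    )
    if stage2.status != "optimal":
        logger.info("validation stage 2 %s for K=%s", stage2.status, sorted(K))
        return (grmax, 0.0)
    return (grmax, stage2.objective + 0.0)


def default_protected(model: MetabolicModel) -> frozenset:
    """Reactions never offered for deletion: every role-designated reaction
    (target and growth, plus uptakes/maintenance when present)."""
    return frozenset(model.roles.values())


def extract_candidate(
    flux: FluxDistribution,
    protected: Iterable[str],
    epsilon: float = FLUX_EPSILON,
) -> frozenset:
    """Collect the candidate knockout set from a first-LP solution.

    K = { j : |x_j| < epsilon } minus the protected reactions (the flux
    threshold is absolute and the inequality strict).
    """
    if flux.status != "optimal":
        raise ContractError(f"cannot extract from a {flux.status} LP")
    protected = frozenset(protected)
    return frozenset(
        rid
        for rid, v in zip(flux.reaction_ids, flux.x)
        if abs(v) < epsilon and rid not in protected
    )


# --------------------------------------------------------------------------
# division: subdivision machinery and the three searches
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchParams:
    """Tunable parameters of the subdivision searches.

    ``min_growth`` / ``min_target`` are the growth-coupling thresholds;
    ``flux_epsilon`` the candidate-extraction threshold; ``n_max`` the
    deepest refinement level (P up to 2**n_max); ``protected`` overrides
    the never-delete set (default: every role reaction).  With
    ``examine_root=True`` (default) the single P=1 cube is solved
    explicitly so its candidate is also tested; with ``False`` it is
    assumed examined-and-feasible and refinement starts at P=2.
    """

    min_growth: float
    min_target: float
    flux_epsilon: float = FLUX_EPSILON
    n_max: int = 5
    protected: Optional[frozenset] = None
    examine_root: bool = True

    def __post_init__(self) -> None:
        if self.min_growth < 0 or self.min_target < 0 or self.flux_epsilon < 0:
            raise ContractError("thresholds must be >= 0")
        if self.n_max < 0:
            raise ContractError("n_max must be >= 0")


@dataclass(frozen=True)
class Cube:
    """One sub-space of the (GR, PR, SF) box at refinement level ``n``."""

    n: int
    i: int
    j: int
    k: int
    box: BoxConstraint

    @property
    def P(self) -> int:
        return 2 ** self.n


@dataclass
class FeasibilityGrid:
    """Per-level exploration state: ``d`` marks cubes to examine, ``c``
    records first-LP feasibility (1) versus infeasible-or-skipped (0)."""

    P: int
    d: np.ndarray
    c: np.ndarray

    @classmethod
    def root(cls, explore: bool = True) -> "FeasibilityGrid":
        return cls(1, np.full((1, 1, 1), explore, dtype=bool), np.zeros((1, 1, 1), dtype=bool))


@dataclass(frozen=True)
class DeletionStrategy:
    """A knockout set with its validated (GRmax, PRmin) and verdict."""

    K: frozenset
    GR: float
    PR: float
    accepted: bool
    found_at: tuple  # (P, i, j, k); k = 0 for grid searches
    lp_count: int = 0

    def as_dict(self) -> dict:
        return {
            "K": sorted(self.K),
            "GR": self.GR,
            "PR": self.PR,
            "accepted": self.accepted,
            "found_at": list(self.found_at),
            "lp_count": self.lp_count,
        }


@dataclass(frozen=True)
class CubeRecord:
    """Trace entry for one cube: status is skipped | infeasible | rejected |
    accepted."""

    P: int
    i: int
    j: int
    k: int
    status: str

    def as_dict(self) -> dict:
        return {"P": self.P, "ijk": [self.i, self.j, self.k], "status": self.status}


@dataclass
class SearchResult:
    """Outcome of a search: the first accepted strategy (or None), the
    theoretical maxima, the machine-readable trace, and LP accounting."""

    strategy: Optional[DeletionStrategy]
    maxima: TheoreticalMaxima
    trace: list
    level_stats: list  # per level: dict of counters
    first_lp_count: int
    total_lp_count: int
    accepted_all: list = field(default_factory=list)
    grids: dict = field(default_factory=dict)  # P -> FeasibilityGrid

    @property
    def success(self) -> bool:
        return self.strategy is not None and self.strategy.accepted

    def trace_dict(self) -> dict:
        return {
            "maxima": dataclasses.asdict(self.maxima),
            "levels": self.level_stats,
            "cubes": [r.as_dict() for r in self.trace],
            "first_lp_count": self.first_lp_count,
            "total_lp_count": self.total_lp_count,
        }


def cube_bounds(maxima: TheoreticalMaxima, n: int, i: int, j: int, k: int) -> BoxConstraint:
    """Box of cube (i, j, k) at level n: GR and PR axes split [0, TM*] into
    P = 2**n closed pieces; the SF axis splits [0, 2*TMSF]."""
    P = 2 ** n
    if not (1 <= i <= P and 1 <= j <= P and 1 <= k <= P):
        raise ContractError(f"indices ({i},{j},{k}) out of range for P={P}")
    return BoxConstraint(
        gr=((i - 1) * maxima.tmgr / P, i * maxima.tmgr / P),
        pr=((j - 1) * maxima.tmpr / P, j * maxima.tmpr / P),
        sf=((k - 1) * 2.0 * maxima.tmsf / P, k * 2.0 * maxima.tmsf / P),
    )


def refine_mask(parent: FeasibilityGrid) -> FeasibilityGrid:
    """Explore-mask at level 2P: each of the 8 children of a cube inherits
    the parent's feasibility flag (children of infeasible cubes are never
    solved)."""
    P2 = 2 * parent.P
    d = np.kron(parent.c, np.ones((2, 2, 2), dtype=bool))
    return FeasibilityGrid(P2, d, np.zeros((P2, P2, P2), dtype=bool))


def _examine_box(
    model: MetabolicModel,
    box: BoxConstraint,
    params: SearchParams,
    protected: frozenset,
    found_at: tuple,
) -> tuple:
    """Run first LP + candidate extraction + validation inside one box.

    Returns (c_flag, strategy_or_None, lp_count)."""
    first = min_total_flux(model, box)
    if first.status == "infeasible":
        return 0, None, 1
    if first.status != "optimal":
        raise SolverError(f"first LP {first.status} in box {box}")
    K = extract_candidate(first, protected, params.flux_epsilon)
    gr, pr = validate_deletion(model, K)
    accepted = gr >= params.min_growth and pr >= params.min_target
    return 1, DeletionStrategy(K, gr, pr, accepted, found_at), 3


def examine_cube(
    model: MetabolicModel, cube: Cube, params: SearchParams
) -> tuple:
    """Examine one cube: first LP in its box; on feasibility, extract the
    candidate K and validate it.  Returns ``(c_flag, strategy_or_None)``."""
    protected = params.protected if params.protected is not None else default_protected(model)
    c_flag, strategy, _ = _examine_box(
        model, cube.box, params, protected, (cube.P, cube.i, cube.j, cube.k)
    )
    return c_flag, strategy


def _prepare(model, medium, params):
    if medium is not None:
        model = apply_medium(model, medium)
    maxima = compute_theoretical_maxima(model, params.min_growth)
    protected = params.protected if params.protected is not None else default_protected(model)
    return model, maxima, protected


def run_dyncubeprod(
    model: MetabolicModel,
    medium: Optional[MediumCondition] = None,
    params: SearchParams = None,
    early_stop: bool = True,
) -> SearchResult:
    """Dynamic subdivision search: double P until a strategy validates.

    Levels n = 0..n_max are visited in order; at each level only cubes whose
    parent's first LP was feasible are examined, in ascending (i, j, k)
    lexicographic order (GR outermost, SF innermost).  The first accepted
    strategy stops the search (``early_stop=False`` exhausts all levels,
    for pruning/economy analysis).  Raises ModelInfeasibleError when the
    base model itself is infeasible.
    """
    if params is None:
        raise ContractError("params is required")
    model, maxima, protected = _prepare(model, medium, params)
    trace: list = []
    level_stats: list = []
    grids: dict = {}
    first_lp = 0
    total_lp = 4  # maxima LPs
    found: Optional[DeletionStrategy] = None
    accepted_all: list = []
    parent: Optional[FeasibilityGrid] = None
    for n in range(0, params.n_max + 1):
        P = 2 ** n
        if n == 0:
            grid = FeasibilityGrid.root(explore=params.examine_root)
            if not params.examine_root:
                grid.c[0, 0, 0] = True  # assumed examined-and-feasible
                grids[P] = grid
                level_stats.append(
                    {"P": P, "examined": 0, "infeasible": 0, "rejected": 0,
                     "accepted": 0, "skipped": 0, "first_lps": 0}
                )
                parent = grid
                continue
        else:
            grid = refine_mask(parent)
        stats = {"P": P, "examined": 0, "infeasible": 0, "rejected": 0,
                 "accepted": 0, "skipped": 0, "first_lps": 0}
        stop = False
        for i in range(1, P + 1):
            for j in range(1, P + 1):
                for k in range(1, P + 1):
                    if not grid.d[i - 1, j - 1, k - 1]:
                        stats["skipped"] += 1
                        trace.append(CubeRecord(P, i, j, k, "skipped"))
                        continue
                    box = cube_bounds(maxima, n, i, j, k)
                    c_flag, strat, nlp = _examine_box(
                        model, box, params, protected, (P, i, j, k)
                    )
                    stats["examined"] += 1
                    stats["first_lps"] += 1
                    first_lp += 1
                    total_lp += nlp
                    grid.c[i - 1, j - 1, k - 1] = bool(c_flag)
                    if c_flag == 0:
                        stats["infeasible"] += 1
                        trace.append(CubeRecord(P, i, j, k, "infeasible"))
                        continue
                    if strat.accepted:
                        stats["accepted"] += 1
                        trace.append(CubeRecord(P, i, j, k, "accepted"))
                        strat = dataclasses.replace(strat, lp_count=total_lp)
                        accepted_all.append(strat)
                        if found is None:
                            found = strat
                        if early_stop:
                            stop = True
                    else:
                        stats["rejected"] += 1
                        trace.append(CubeRecord(P, i, j, k, "rejected"))
                    if stop:
                        break
                if stop:
                    break
            if stop:
                break
        grids[P] = grid
        level_stats.append(stats)
        logger.info(
            "level P=%d: examined=%d infeasible=%d rejected=%d accepted=%d skipped=%d",
            P, stats["examined"], stats["infeasible"], stats["rejected"],
            stats["accepted"], stats["skipped"],
        )
        if stop:
            break
        parent = grid
    return SearchResult(
        found, maxima, trace, level_stats, first_lp, total_lp, accepted_all, grids
    )


def run_cubeprod(
    model: MetabolicModel,
    medium: Optional[MediumCondition] = None,
    params: SearchParams = None,
    P: int = 2,
    early_stop: bool = False,
) -> SearchResult:
    """Static cube search: examine all P**3 cubes of the (GR, PR, SF) box.

    Returns every accepted strategy found (``accepted_all``) plus the
    feasibility grid for analysis; ``strategy`` is the first accepted one
    in (i, j, k) order.
    """
    if params is None:
        raise ContractError("params is required")
    if P < 1:
        raise ContractError("P must be >= 1")
    n = max(0, int(round(math.log2(P))))
    if 2 ** n != P:
        raise ContractError(f"P must be a power of two, got {P}")
    model, maxima, protected = _prepare(model, medium, params)
    grid = FeasibilityGrid(P, np.ones((P, P, P), dtype=bool), np.zeros((P, P, P), dtype=bool))
    trace: list = []
    stats = {"P": P, "examined": 0, "infeasible": 0, "rejected": 0,
             "accepted": 0, "skipped": 0, "first_lps": 0}
    first_lp, total_lp = 0, 4
    found = None
    accepted_all: list = []
    stop = False
    for i in range(1, P + 1):
        for j in range(1, P + 1):
            for k in range(1, P + 1):
                box = cube_bounds(maxima, n, i, j, k)
                c_flag, strat, nlp = _examine_box(
                    model, box, params, protected, (P, i, j, k)
                )
                stats["examined"] += 1
                stats["first_lps"] += 1
                first_lp += 1
                total_lp += nlp
                grid.c[i - 1, j - 1, k - 1] = bool(c_flag)
                if c_flag == 0:
                    stats["infeasible"] += 1
                    trace.append(CubeRecord(P, i, j, k, "infeasible"))
                elif strat.accepted:
                    stats["accepted"] += 1
                    trace.append(CubeRecord(P, i, j, k, "accepted"))
                    strat = dataclasses.replace(strat, lp_count=total_lp)
                    accepted_all.append(strat)
                    if found is None:
                        found = strat
                    if early_stop:
                        stop = True
                else:
                    stats["rejected"] += 1
                    trace.append(CubeRecord(P, i, j, k, "rejected"))
                if stop:
                    break
            if stop:
                break
        if stop:
            break
    return SearchResult(
        found, maxima, trace, [stats], first_lp, total_lp, accepted_all, {P: grid}
    )


def run_gridprod(
    model: MetabolicModel,
    medium: Optional[MediumCondition] = None,
    params: SearchParams = None,
    P: int = 2,
    early_stop: bool = False,
) -> SearchResult:
    """Static 2-D grid search over GR x PR (no SF constraint in the first
    LP); otherwise identical per-cell candidate extraction and validation."""
    if params is None:
        raise ContractError("params is required")
    if P < 1:
        raise ContractError("P must be >= 1")
    model, maxima, protected = _prepare(model, medium, params)
    trace: list = []
    stats = {"P": P, "examined": 0, "infeasible": 0, "rejected": 0,
             "accepted": 0, "skipped": 0, "first_lps": 0}
    first_lp, total_lp = 0, 4
    found = None
    accepted_all: list = []
    stop = False
    for i in range(1, P + 1):
        for j in range(1, P + 1):
            box = BoxConstraint(
                gr=((i - 1) * maxima.tmgr / P, i * maxima.tmgr / P),
                pr=((j - 1) * maxima.tmpr / P, j * maxima.tmpr / P),
                sf=(0.0, math.inf),
            )
            c_flag, strat, nlp = _examine_box(model, box, params, protected, (P, i, j, 0))
            stats["examined"] += 1
            stats["first_lps"] += 1
            first_lp += 1
            total_lp += nlp
            if c_flag == 0:
                stats["infeasible"] += 1
                trace.append(CubeRecord(P, i, j, 0, "infeasible"))
            elif strat.accepted:
                stats["accepted"] += 1
                trace.append(CubeRecord(P, i, j, 0, "accepted"))
                strat = dataclasses.replace(strat, lp_count=total_lp)
                accepted_all.append(strat)
                if found is None:
                    found = strat
                if early_stop:
                    stop = True
            else:
                stats["rejected"] += 1
                trace.append(CubeRecord(P, i, j, 0, "rejected"))
            if stop:
                break
        if stop:
            break
    return SearchResult(found, maxima, trace, [stats], first_lp, total_lp, accepted_all, {})


# --------------------------------------------------------------------------
# cli back-end: configuration, result records, batch sweeps, fixtures
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a single design run (the CLI's parameter record)."""

    model_path: str
    target: str
    format: Optional[str] = None  # sbml | bigg_json | native | None (auto)
    method: str = "dyncubeprod"  # gridprod | cubeprod | dyncubeprod
    condition: Optional[str] = None  # aerobic | anaerobic | None (no medium)
    gur: float = DEFAULT_GUR
    our: float = DEFAULT_OUR_AEROBIC
    ngam: float = DEFAULT_NGAM
    min_growth: float = 1e-3
    min_target: float = 1e-3
    flux_epsilon: float = FLUX_EPSILON
    n_max: int = 5
    out: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("gridprod", "cubeprod", "dyncubeprod"):
            raise ContractError(f"unknown method {self.method!r}")
        if self.condition not in (None, "aerobic", "anaerobic"):
            raise ContractError(f"unknown condition {self.condition!r}")
        if self.condition == "anaerobic":
            self.our = 0.0

    def medium(self) -> Optional[MediumCondition]:
        if self.condition is None:
            return None
        return MediumCondition(self.gur, self.our, self.ngam)

    def search_params(self) -> SearchParams:
        return SearchParams(
            min_growth=self.min_growth,
            min_target=self.min_target,
            flux_epsilon=self.flux_epsilon,
            n_max=self.n_max,
        )

    def echo(self) -> dict:
        return {
            "model": self.model_path,
            "target": self.target,
            "method": self.method,
            "condition": self.condition,
            "gur": self.gur,
            "our": self.our,
            "ngam": self.ngam,
            "min_growth": self.min_growth,
            "min_target": self.min_target,
            "flux_epsilon": self.flux_epsilon,
            "n_max": self.n_max,
            "seed": self.seed,
        }


def _design_once(model: MetabolicModel, config: RunConfig) -> tuple:
    """Run the configured method for one target; returns (record, result)."""
    model = add_target_exchange(model, config.target)
    params = config.search_params()
    medium = config.medium()
    if config.method == "dyncubeprod":
        result = run_dyncubeprod(model, medium, params)
    elif config.method == "cubeprod":
        result = run_cubeprod(model, medium, params, P=2 ** config.n_max, early_stop=True)
    else:
        result = run_gridprod(model, medium, params, P=2 ** config.n_max, early_stop=True)
    strat = result.strategy
    record = {
        "target": config.target,
        "parameters": config.echo(),
        "maxima": dataclasses.asdict(result.maxima),
        "accepted": bool(result.success),
        "strategy": strat.as_dict() if strat else None,
        "levels": result.level_stats,
        "first_lp_count": result.first_lp_count,
        "total_lp_count": result.total_lp_count,
    }
    return record, result


def cmd_design(config: RunConfig) -> int:
    """Single-target design run; writes a self-describing result record.

    Exit codes: 0 accepted strategy found, 3 no strategy, 4 data error
    (model/target), 5 solver error.
    """
    try:
        model = read_model(config.model_path, config.format)
    except (FormatError, FileNotFoundError, OSError) as exc:
        logger.error("cannot read model: %s", exc)
        return EXIT_DATA
    try:
        record, _ = _design_once(model, config)
    except (UnknownIdError, RoleError) as exc:
        logger.error("bad target or roles: %s", exc)
        return EXIT_DATA
    except ModelInfeasibleError as exc:
        logger.error("model infeasible: %s", exc)
        return EXIT_DATA
    except SolverError as exc:
        logger.error("solver failure: %s", exc)
        return EXIT_SOLVER
    if config.out:
        with open(config.out, "w") as fh:
            json.dump(record, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return EXIT_ACCEPTED if record["accepted"] else EXIT_NO_STRATEGY


def cmd_batch(config: RunConfig, targets_path: str) -> int:
    """Batch sweep over a file of target metabolite ids (one per line).

    Writes one TSV row per target plus an aggregate success ratio; unknown
    ids are logged and excluded from the denominator.  Resumable: rows
    already present in the output TSV are not recomputed.
    """
    with open(targets_path) as fh:
        targets = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not targets:
        logger.error("empty target list %s", targets_path)
        return EXIT_USAGE
    try:
        model = read_model(config.model_path, config.format)
    except (FormatError, FileNotFoundError, OSError) as exc:
        logger.error("cannot read model: %s", exc)
        return EXIT_DATA
    out = config.out or "batch_results.tsv"
    done: dict = {}
    if os.path.exists(out):
        with open(out) as fh:
            for ln in fh:
                if ln.startswith("#") or ln.startswith("target\t"):
                    continue
                parts = ln.rstrip("\n").split("\t")
                if parts and parts[0]:
                    done[parts[0]] = ln.rstrip("\n")
    rows = []
    for t in targets:
        if t in done:
            rows.append(done[t])
            continue
        if t not in model.metabolite_ids:
            logger.warning("unknown target metabolite %s: skipped", t)
            rows.append(f"{t}\tskipped\t\t\t")
            continue
        cfg = dataclasses.replace(config, target=t, out=None)
        try:
            record, _ = _design_once(model, cfg)
        except (SolverError, ModelInfeasibleError) as exc:
            logger.error("target %s failed: %s", t, exc)
            rows.append(f"{t}\terror\t\t\t")
            continue
        strat = record["strategy"]
        status = "accepted" if record["accepted"] else "rejected"
        kset = ";".join(strat["K"]) if strat else ""
        gr = f"{strat['GR']:.6g}" if strat else ""
        pr = f"{strat['PR']:.6g}" if strat else ""
        rows.append(f"{t}\t{status}\t{kset}\t{gr}\t{pr}")
    attempted = [r for r in rows if "\tskipped\t" not in r]
    accepted = [r for r in rows if "\taccepted\t" in r]
    ratio = len(accepted) / len(attempted) if attempted else 0.0
    with open(out, "w") as fh:
        fh.write("target\tstatus\tK\tGR\tPR\n")
        for r in rows:
            fh.write(r + "\n")
        fh.write(f"# success_ratio\t{len(accepted)}/{len(attempted)}\t{ratio:.4f}\n")
    logger.info("batch: %d/%d accepted (%.2f%%)", len(accepted), len(attempted), 100 * ratio)
    return EXIT_ACCEPTED


def cmd_fixture(kind: str, seed: int, out: str, n_metabolites: int = 5, n_reactions: int = 10) -> int:
    """Write the toy fixture or a seeded random network as native JSON."""
    if kind == "toy":
        model = build_toy_network()
    elif kind == "random":
        model = generate_random_network(n_metabolites, n_reactions, seed)
    else:
        raise ContractError(f"unknown fixture kind {kind!r}")
    write_model(model, out)
    return EXIT_ACCEPTED
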