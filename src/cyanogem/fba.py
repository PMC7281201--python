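"""Flux balance analysis and parsimonious FBA.

Linear programs over steady-state flux vectors: maximize/minimize a
linear objective c·v subject to N·v = 0 and per-reaction bounds, or — for
parsimonious FBA — minimize total absolute flux Σ|v| under fixed growth,
an O2-evolution window and a fixed ATP-maintenance flux.  The absolute
value is linearized by splitting every flux into non-negative forward
and reverse parts (v = v⁺ − v⁻).  Solved with scipy's HiGHS backend;
variable order is the sorted reaction ids, so results are deterministic.

Flux convention: exchange reactions are written ``met ⟶ ∅`` so negative
flux is uptake and positive flux secretion, all in mmol·(gDCW·h)⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_matrix

log = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
STEADY_STATE_TOL = 1e-6

#: metabolite base names whose exchanges stay open in a photoautotrophic
#: medium (inorganic carbon, light, major ions, water, oxygen)
PHOTOAUTOTROPHIC_OPEN = {
    "co2",
    "hco3",
    "photon",
    "no3",
    "hno3",
    "nh3",
    "nh4",
    "pi",
    "so4",
    "h2o",
    "h",
    "o2",
    "mg2",
    "k",
    "na1",
    "fe3",
    "ca2",
    "cl",
}


@dataclass
class SimulationConstraints:
    """Constraint settings for photoautotrophic simulations.

    fixed_growth: growth rate x (h⁻¹) to pin the biomass flux to, or None.
    o2_evolution: (central value, halfwidth) window on the O2 exchange
        flux, encoded as bounds [y−h, y+h]; None leaves O2 free.
    medium: exchange-reaction id → (lb, ub) overrides.
    ngam_flux: flux fixed through the ATP-maintenance reaction.
    """

    fixed_growth: float | None = None
    o2_evolution: tuple[float, float] | None = None
    medium: dict[str, tuple[float, float]] = field(default_factory=dict)
    ngam_flux: float | None = None
    biomass_reaction: str | None = None
    o2_exchange: str | None = None
    maintenance_reaction: str | None = None
    closed_exchanges: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.o2_evolution is not None and self.o2_evolution[1] < 0:
            raise ValueError("O2 window halfwidth must be >= 0")


@dataclass
class ObjectiveSpec:
    """Linear objective: reaction weights c and a sense."""

    coefficients: dict[str, float]
    sense: str = "max"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("objective must reference at least one reaction")
        if self.sense not in ("max", "min"):
            raise ValueError(f"unknown sense {self.sense!r}")

    @classmethod
    def maximize(cls, reaction_id: str) -> "ObjectiveSpec":
        return cls({reaction_id: 1.0}, "max")


@dataclass
class FluxState:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    total_flux: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def exchange_for(model: MetabolicModel, base: str) -> str | None:
    """Exchange-reaction id whose single metabolite has base name ``base``.

    The base name is the metabolite id with a trailing ``_<compartment>``
    tag stripped (``co2_e`` → ``co2``).
    """
    for rxn in model.exchanges():
        (met_id,) = rxn.stoichiometry
        stem = met_id.rsplit("_", 1)[0] if "_" in met_id else met_id
        if stem.lower() == base.lower():
            return rxn.id
    return None


def _resolve_special(model: MetabolicModel, constraints: SimulationConstraints):
    biomass = constraints.biomass_reaction
    if biomass is None:
        candidates = [r.id for r in model.reactions.values() if r.category == "biomass"]
        biomass = model.objective if model.objective in model.reactions else None
        if biomass is None and len(candidates) == 1:
            biomass = candidates[0]
    o2x = constraints.o2_exchange or exchange_for(model, "o2")
    maint = constraints.maintenance_reaction
    if maint is None:
        candidates = [
            r.id for r in model.reactions.values() if r.category == "maintenance"
        ]
        if len(candidates) == 1:
            maint = candidates[0]
    return biomass, o2x, maint


def _effective_bounds(
    model: MetabolicModel,
    constraints: SimulationConstraints | None,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    bounds = {rid: model.reactions[rid].bounds for rid in model.reaction_ids}
    if constraints is None:
        if overrides:
            bounds.update(overrides)
        return bounds
    for rid, b in constraints.medium.items():
        if rid not in bounds:
            raise KeyError(f"medium references unknown reaction {rid!r}")
        bounds[rid] = (float(b[0]), float(b[1]))
    biomass, o2x, maint = _resolve_special(model, constraints)
    if constraints.fixed_growth is not None:
        if biomass is None:
            raise ValueError("fixed_growth set but no biomass reaction identified")
        x = constraints.fixed_growth
        bounds[biomass] = (x, x)
    if constraints.o2_evolution is not None:
        if o2x is None:
            raise ValueError("O2 window set but no O2 exchange found")
        y, h = constraints.o2_evolution
        bounds[o2x] = (y - h, y + h)
    if constraints.ngam_flux is not None:
        if maint is None:
            raise ValueError("ngam_flux set but no maintenance reaction identified")
        bounds[maint] = (constraints.ngam_flux, constraints.ngam_flux)
    if overrides:
        # applied last and replacing any medium/fixation setting: a
        # reaction deletion zeroes the flux even where a constraint
        # fixed it (the standard knockout convention)
        for rid, b in overrides.items():
            if rid not in bounds:
                raise KeyError(f"override references unknown reaction {rid!r}")
            bounds[rid] = (float(b[0]), float(b[1]))
    return bounds


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    return res, _STATUS.get(res.status, "failed")


def _infeasibility_hint(bounds: dict[str, tuple[float, float]]) -> str:
    fixed = [f"{rid}={lb:g}" for rid, (lb, ub) in sorted(bounds.items()) if lb == ub and lb != 0]
    return "fixed fluxes: " + (", ".join(fixed) if fixed else "(none)")


def solve_fba(
    model: MetabolicModel,
    objective: ObjectiveSpec | str,
    constraints: SimulationConstraints | None = None,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxState:
    """Solve max/min c·v subject to N·v = 0 and bounds.

    ``bound_overrides`` replace any other bound setting, including
    medium and fixation encoding — used for reaction deletions.
    """
    if isinstance(objective, str):
        objective = ObjectiveSpec.maximize(objective)
    if not model.reactions:
        raise ValueError("model has no reactions")
    unknown = [r for r in objective.coefficients if r not in model.reactions]
    if unknown:
        raise KeyError(f"objective references unknown reactions {unknown}")

    N, met_ids, rxn_ids = build_matrix(model)
    bounds = _effective_bounds(model, constraints, bound_overrides)
    if any(lb > ub for lb, ub in bounds.values()):
        return FluxState({}, float("nan"), "infeasible")
    sign = -1.0 if objective.sense == "max" else 1.0
    c = np.zeros(len(rxn_ids))
    for rid, w in objective.coefficients.items():
        c[rxn_ids.index(rid)] = sign * w
    lp_bounds = [bounds[rid] for rid in rxn_ids]
    res, status = _lp(c, N, np.zeros(N.shape[0]), lp_bounds)
    if status != "optimal":
        if status == "infeasible":
            log.info("FBA infeasible; %s", _infeasibility_hint(bounds))
        return FluxState({}, float("nan"), status)
    fluxes = dict(zip(rxn_ids, res.x))
    obj = float(sum(w * fluxes[rid] for rid, w in objective.coefficients.items()))
    _check_steady_state(N, res.x)
    return FluxState(fluxes, obj, "optimal")


def _split_system(model: MetabolicModel, bounds: dict[str, tuple[float, float]]):
    """Forward/reverse split: v = v⁺ − v⁻ with both parts ≥ 0."""
    N, met_ids, rxn_ids = build_matrix(model)
    A_eq = sparse.hstack([N, -N], format="csr")
    lp_bounds = []
    for rid in rxn_ids:
        lb, ub = bounds[rid]
        lp_bounds.append((max(lb, 0.0), max(ub, 0.0)))  # v⁺
    for rid in rxn_ids:
        lb, ub = bounds[rid]
        lp_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # v⁻
    return A_eq, rxn_ids, lp_bounds, N


def solve_pfba(
    model: MetabolicModel,
    constraints: SimulationConstraints | None = None,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxState:
    """Parsimonious FBA: minimize Σ|v| under the given fixations."""
    if not model.reactions:
        raise ValueError("model has no reactions")
    bounds = _effective_bounds(model, constraints, bound_overrides)
    if any(lb > ub for lb, ub in bounds.values()):
        return FluxState({}, float("nan"), "infeasible")
    A_eq, rxn_ids, lp_bounds, N = _split_system(model, bounds)
    n = len(rxn_ids)
    c = np.ones(2 * n)
    res, status = _lp(c, A_eq, np.zeros(A_eq.shape[0]), lp_bounds)
    if status != "optimal":
        if status == "infeasible":
            log.info("pFBA infeasible; %s", _infeasibility_hint(bounds))
        return FluxState({}, float("nan"), status)
    v = res.x[:n] - res.x[n:]
    total = float(np.sum(np.abs(v)))
    _check_steady_state(N, v)
    return FluxState(dict(zip(rxn_ids, v)), total, "optimal", total_flux=total)


def _check_steady_state(N, v) -> None:
    imbalance = float(np.max(np.abs(N @ v))) if N.shape[0] else 0.0
    if imbalance > STEADY_STATE_TOL:
        raise RuntimeError(f"steady-state violated: max imbalance {imbalance:.2e}")


def flux_variability(
    model: MetabolicModel,
    constraints: SimulationConstraints | None = None,
    reactions: list[str] | None = None,
    at_pfba_optimum: bool = False,
    optimum_slack: float = 1e-9,
) -> dict[str, tuple[float, float]]:
    """Min/max flux per reaction, optionally within the pFBA optimum.

    With ``at_pfba_optimum`` the total-flux value of :func:`solve_pfba`
    is added as the constraint Σ(v⁺+v⁻) ≤ optimum (plus slack), so the
    ranges expose degeneracy of the parsimonious solution.
    """
    bounds = _effective_bounds(model, constraints)
    A_eq, rxn_ids, lp_bounds, _ = _split_system(model, bounds)
    n = len(rxn_ids)
    A_ub = b_ub = None
    if at_pfba_optimum:
        state = solve_pfba(model, constraints)
        if not state.optimal:
            raise RuntimeError(f"pFBA not optimal ({state.status}); no FVA possible")
        A_ub = sparse.csr_matrix(np.ones((1, 2 * n)))
        b_ub = np.array([state.total_flux * (1 + optimum_slack) + optimum_slack])
    targets = sorted(reactions) if reactions is not None else rxn_ids
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(2 * n)
        c[j], c[n + j] = 1.0, -1.0
        lo_res, lo_st = _lp(c, A_eq, np.zeros(A_eq.shape[0]), lp_bounds, A_ub, b_ub)
        hi_res, hi_st = _lp(-c, A_eq, np.zeros(A_eq.shape[0]), lp_bounds, A_ub, b_ub)
        if lo_st != "optimal" or hi_st != "optimal":
            raise RuntimeError(f"FVA subproblem for {rid} ended {lo_st}/{hi_st}")
        lo = lo_res.x[j] - lo_res.x[n + j]
        hi = hi_res.x[j] - hi_res.x[n + j]
        out[rid] = (float(lo), float(hi))
    return out


def set_photoautotrophic_medium(
    model: MetabolicModel,
    base: SimulationConstraints | None = None,
    open_bound: float = 1000.0,
) -> SimulationConstraints:
    """Constrain exchanges to a photoautotrophic medium.

    CO2/bicarbonate, photon, nitrate, phosphate, sulfate, water, protons,
    O2 and common ions stay open in both directions; every other
    (organic-carbon) exchange has its uptake bound set to zero, secretion
    left open.  Returns a new :class:`SimulationConstraints` whose medium
    records the applied bounds and whose ``closed_exchanges`` lists the
    closed carbon sources.
    """
    constraints = SimulationConstraints(
        fixed_growth=base.fixed_growth if base else None,
        o2_evolution=base.o2_evolution if base else None,
        medium=dict(base.medium) if base else {},
        ngam_flux=base.ngam_flux if base else None,
        biomass_reaction=base.biomass_reaction if base else None,
        o2_exchange=base.o2_exchange if base else None,
        maintenance_reaction=base.maintenance_reaction if base else None,
    )
    exchanges = model.exchanges()
    if not exchanges:
        raise ValueError("model has no exchange reactions")
    found_photon = False
    closed: list[str] = []
    for rxn in exchanges:
        (met_id,) = rxn.stoichiometry
        stem = (met_id.rsplit("_", 1)[0] if "_" in met_id else met_id).lower()
        if stem == "photon":
            found_photon = True
        if stem in PHOTOAUTOTROPHIC_OPEN:
            # ensure uptake is possible but keep a tighter model bound
            # (e.g. a photon cap) if one is already set
            lb = rxn.lower_bound if rxn.lower_bound < 0 else -open_bound
            constraints.medium.setdefault(rxn.id, (lb, rxn.upper_bound))
        else:
            # closed for uptake; secretion stays as the model allows
            constraints.medium.setdefault(rxn.id, (0.0, rxn.upper_bound))
            closed.append(rxn.id)
    if not found_photon:
        raise ValueError(
            "no photon exchange found: model is not photoautotrophic-ready"
        )
    constraints.closed_exchanges = closed
    return constraints
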