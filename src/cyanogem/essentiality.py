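"""Reaction essentiality, active-reaction classification, energy scans.

Essentiality follows the reaction-deletion protocol: one LP per
reaction, bounds pinned to zero, growth re-maximized; a reaction is
essential if the deletion drops maximal growth to ≤ 1e-4 h⁻¹.  Active
reactions are those carrying |flux| ≥ 1e-8 mmol·(gDCW·h)⁻¹ in a given
flux state.  The GAM/NGAM sensitivity scan rebuilds the biomass
equation and maintenance bound for each parameter pair and re-solves
parsimonious FBA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .biomass import BiomassComposition, EnergyParameters, compose_biomass_reaction
from .fba import (
    FluxState,
    ObjectiveSpec,
    SimulationConstraints,
    exchange_for,
    flux_variability,
    solve_fba,
    solve_pfba,
)
from .model import MetabolicModel

log = logging.getLogger(__name__)


@dataclass
class AnalysisSettings:
    essentiality_growth_threshold: float = 1e-4  # h⁻¹
    active_flux_threshold: float = 1e-8  # mmol·(gDCW·h)⁻¹

    def __post_init__(self) -> None:
        if self.essentiality_growth_threshold <= 0:
            raise ValueError("essentiality growth threshold must be > 0")
        if self.active_flux_threshold <= 0:
            raise ValueError("active flux threshold must be > 0")


@dataclass
class EssentialityReport:
    growth_after_deletion: dict[str, float]
    essential: set[str]
    baseline_growth: float
    by_subsystem: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_essential(self) -> int:
        return len(self.essential)

    @property
    def n_screened(self) -> int:
        return len(self.growth_after_deletion)

    def to_frame(self, model: MetabolicModel) -> pd.DataFrame:
        rows = [
            {
                "reaction": rid,
                "subsystem": model.reactions[rid].subsystem,
                "growth_after_deletion": g,
                "essential": rid in self.essential,
            }
            for rid, g in sorted(self.growth_after_deletion.items())
        ]
        return pd.DataFrame(rows)


def _screen_constraints(
    constraints: SimulationConstraints | None,
) -> SimulationConstraints | None:
    """Release the growth fixation; keep medium, O2 window and NGAM."""
    if constraints is None or constraints.fixed_growth is None:
        return constraints
    log.info("essentiality screen: releasing fixed growth %g", constraints.fixed_growth)
    return replace(constraints, fixed_growth=None)


def essential_reactions(
    model: MetabolicModel,
    constraints: SimulationConstraints | None = None,
    settings: AnalysisSettings | None = None,
    objective: str | None = None,
    reactions: list[str] | None = None,
) -> EssentialityReport:
    """Single-reaction deletion screen.

    Each reaction in turn has its bounds set to [0, 0] and growth is
    re-maximized; infeasible deletions count as zero growth.  Bounds are
    restored after every deletion.  Screening order is the sorted
    reaction ids and results are order-invariant.
    """
    settings = settings or AnalysisSettings()
    objective = objective or model.objective
    if objective is None:
        raise ValueError("no biomass objective defined")
    constraints = _screen_constraints(constraints)
    baseline = solve_fba(model, ObjectiveSpec.maximize(objective), constraints)
    if not baseline.optimal:
        raise RuntimeError(
            f"baseline maximization is {baseline.status}; screen aborted "
            "(check medium and maintenance constraints)"
        )
    targets = sorted(reactions) if reactions is not None else model.reaction_ids
    growth: dict[str, float] = {}
    for rid in targets:
        state = solve_fba(
            model,
            ObjectiveSpec.maximize(objective),
            constraints,
            bound_overrides={rid: (0.0, 0.0)},
        )
        growth[rid] = state.objective_value if state.optimal else 0.0
    essential = {
        rid
        for rid, g in growth.items()
        if g <= settings.essentiality_growth_threshold
    }
    by_sub: dict[str, dict[str, int]] = {}
    for rid in targets:
        sub = model.reactions[rid].subsystem or "(none)"
        entry = by_sub.setdefault(sub, {"total": 0, "essential": 0})
        entry["total"] += 1
        entry["essential"] += rid in essential
    return EssentialityReport(growth, essential, baseline.objective_value, by_sub)


def active_reactions(
    flux_state: FluxState,
    settings: AnalysisSettings | None = None,
    model: MetabolicModel | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Reactions with |flux| at or above the activity threshold.

    With a model, also returns the per-subsystem histogram of active
    reaction counts.
    """
    settings = settings or AnalysisSettings()
    if not flux_state.optimal:
        raise ValueError(f"flux state is {flux_state.status}, not optimal")
    active = {
        rid
        for rid, v in flux_state.fluxes.items()
        if abs(v) >= settings.active_flux_threshold
    }
    by_sub: dict[str, int] = {}
    if model is not None:
        for rid in active:
            sub = model.reactions[rid].subsystem or "(none)"
            by_sub[sub] = by_sub.get(sub, 0) + 1
    return active, by_sub


def active_in_any_optimum(
    model: MetabolicModel,
    constraints: SimulationConstraints | None = None,
    settings: AnalysisSettings | None = None,
) -> set[str]:
    """Reactions active in at least one minimal-total-flux solution.

    Flux-variability ranges at the pFBA optimum flag the count as
    range-dependent when the parsimonious optimum is degenerate.
    """
    settings = settings or AnalysisSettings()
    ranges = flux_variability(model, constraints, at_pfba_optimum=True)
    return {
        rid
        for rid, (lo, hi) in ranges.items()
        if max(abs(lo), abs(hi)) >= settings.active_flux_threshold
    }


def subsystem_summary(
    model: MetabolicModel,
    active: set[str],
    essential: set[str],
) -> pd.DataFrame:
    """Per-subsystem table of total / active / essential reaction counts."""
    rows: dict[str, dict[str, int]] = {}
    for rid, rxn in model.reactions.items():
        sub = rxn.subsystem or "(none)"
        row = rows.setdefault(sub, {"total": 0, "active": 0, "essential": 0})
        row["total"] += 1
        row["active"] += rid in active
        row["essential"] += rid in essential
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("subsystem")
        .sort_index()
        .reset_index()
    )


def energy_sensitivity_scan(
    model: MetabolicModel,
    composition: BiomassComposition,
    metabolite_map: dict[str, str],
    gam_values: list[float],
    ngam_values: list[float],
    constraints: SimulationConstraints,
    central_subsystems: tuple[str, ...] = (
        "Calvin cycle",
        "Glycolysis",
        "TCA cycle",
        "Carbohydrate metabolism",
    ),
) -> pd.DataFrame:
    """pFBA re-solved over a GAM × NGAM grid.

    For each pair the biomass equation is rebuilt from the composition
    with the new GAM, the maintenance fixation is set to the new NGAM,
    and parsimonious FBA is re-run.  Reported per cell: photon uptake,
    O2 evolution, CO2 uptake, total flux and the L1 distance of
    central-carbon fluxes from the base solution.  Infeasible cells are
    marked and the scan continues.
    """
    biomass_id = constraints.biomass_reaction or model.objective
    if biomass_id is None:
        raise ValueError("cannot identify the biomass reaction to rebuild")
    photon_x = exchange_for(model, "photon")
    co2_x = exchange_for(model, "co2")
    o2_x = constraints.o2_exchange or exchange_for(model, "o2")

    base = solve_pfba(model, constraints)
    if not base.optimal:
        raise RuntimeError(f"base pFBA is {base.status}; scan aborted")
    central = [
        rid
        for rid in model.reaction_ids
        if model.reactions[rid].subsystem in central_subsystems
    ]

    rows = []
    for gam in gam_values:
        for ngam in ngam_values:
            work = model.copy()
            biomass_met = next(
                (
                    m
                    for m, c in work.reactions[biomass_id].stoichiometry.items()
                    if c > 0 and "biomass" in m.lower()
                ),
                None,
            )
            old = work.remove_reaction(biomass_id)
            eq = compose_biomass_reaction(
                composition,
                EnergyParameters(gam=gam, ngam=ngam),
                metabolite_map=metabolite_map,
                reaction_id=biomass_id,
                biomass_metabolite=biomass_met,
            )
            eq.reaction.subsystem = old.subsystem
            work.add_reaction(eq.reaction)
            cons = replace(constraints, ngam_flux=ngam)
            state = solve_pfba(work, cons)
            row = {"gam": gam, "ngam": ngam, "status": state.status}
            if state.optimal:
                row.update(
                    photon_uptake=-state.fluxes[photon_x] if photon_x else float("nan"),
                    o2_evolution=state.fluxes[o2_x] if o2_x else float("nan"),
                    co2_uptake=-state.fluxes[co2_x] if co2_x else float("nan"),
                    total_flux=state.total_flux,
                    central_l1=sum(
                        abs(state.fluxes[r] - base.fluxes[r]) for r in central
                    ),
                )
            rows.append(row)
    return pd.DataFrame(rows)
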