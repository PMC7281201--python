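"""Model-quality checks: precursor gaps, infeasible loops, free ATP.

All checks operate on temporarily modified bounds and restore the model
exactly; none of them mutates reaction content.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field

from .biomass import BiomassEquation
from .fba import ObjectiveSpec, SimulationConstraints, solve_fba, solve_pfba
from .model import EVIDENCE_TAGS, MetabolicModel, Reaction

PRODUCIBILITY_TOL = 1e-8
LOOP_FLUX_TOL = 1e-8


@contextmanager
def _temporary_bounds(model: MetabolicModel):
    saved = {rid: r.bounds for rid, r in model.reactions.items()}
    try:
        yield
    finally:
        for rid, b in saved.items():
            if rid in model.reactions:
                model.reactions[rid].bounds = b


@contextmanager
def _temporary_demand(model: MetabolicModel, met_id: str):
    rid = f"__DM_{met_id}"
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry={met_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            category="demand",
        )
    )
    try:
        yield rid
    finally:
        model.remove_reaction(rid)


@dataclass
class GapEntry:
    precursor: str
    producible: bool
    max_flux: float
    structurally_missing: bool = False
    blocking_metabolites: list[str] = field(default_factory=list)


@dataclass
class GapReport:
    entries: list[GapEntry]

    @property
    def gaps(self) -> list[str]:
        return [e.precursor for e in self.entries if not e.producible]

    @property
    def all_producible(self) -> bool:
        return all(e.producible for e in self.entries)

    def to_json(self) -> str:
        return json.dumps(
            [e.__dict__ for e in self.entries], indent=2, sort_keys=True
        )

    def __str__(self) -> str:
        lines = []
        for e in self.entries:
            state = (
                "missing from model"
                if e.structurally_missing
                else ("producible" if e.producible else "GAP")
            )
            extra = (
                f" (blocked at: {', '.join(e.blocking_metabolites)})"
                if e.blocking_metabolites
                else ""
            )
            lines.append(f"{e.precursor:30s} {state:18s} max flux {e.max_flux:.6g}{extra}")
        return "\n".join(lines)


def _max_production(
    model: MetabolicModel, met_id: str, constraints: SimulationConstraints | None
) -> float:
    with _temporary_demand(model, met_id) as rid:
        state = solve_fba(model, ObjectiveSpec.maximize(rid), constraints)
        return state.objective_value if state.optimal else 0.0


def find_gaps(
    model: MetabolicModel,
    biomass: BiomassEquation | list[str],
    constraints: SimulationConstraints | None = None,
    trace_blocking: bool = True,
) -> GapReport:
    """Check producibility of every biomass precursor.

    For each precursor a temporary demand reaction is added and
    maximized under the given (photoautotrophic) constraints; the
    precursor is producible iff the maximum exceeds 1e-8.  For gaps, the
    substrates of candidate producing reactions are themselves tested to
    name the blocking metabolites.
    """
    precursors = (
        sorted(biomass.precursor_coefficients)
        if isinstance(biomass, BiomassEquation)
        else sorted(biomass)
    )
    entries: list[GapEntry] = []
    memo: dict[str, bool] = {}

    def producible(met: str) -> bool:
        if met not in memo:
            memo[met] = _max_production(model, met, constraints) > PRODUCIBILITY_TOL
        return memo[met]

    for met in precursors:
        if met not in model.metabolites:
            entries.append(GapEntry(met, False, 0.0, structurally_missing=True))
            continue
        vmax = _max_production(model, met, constraints)
        ok = vmax > PRODUCIBILITY_TOL
        blocking: list[str] = []
        if not ok and trace_blocking:
            producers = [
                r
                for r in model.reactions.values()
                if r.stoichiometry.get(met, 0) > 0
                or (r.stoichiometry.get(met, 0) < 0 and r.lower_bound < 0)
            ]
            substrates = {
                m
                for r in producers
                for m, c in r.stoichiometry.items()
                if c < 0 and m != met
            }
            blocking = sorted(m for m in substrates if not producible(m))
        entries.append(GapEntry(met, ok, vmax, blocking_metabolites=blocking))
    return GapReport(entries)


@dataclass
class LoopReport:
    feasible: bool
    loop_reactions: set[str]
    fixation_value: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "feasible": self.feasible,
                "loop_reactions": sorted(self.loop_reactions),
                "fixation_value": self.fixation_value,
            },
            indent=2,
        )


def detect_infeasible_loops(
    model: MetabolicModel,
    atp_synthase_id: str,
    fixation: float = 1.0,
) -> LoopReport:
    """Thermodynamically infeasible loop test.

    All exchange fluxes are fixed to zero and the ATP synthase flux to a
    positive value.  If the system is still feasible, the minimal-total-
    flux solution's nonzero reactions are the loop members; an
    infeasible system means the model is loop-free at this entry point.
    """
    if atp_synthase_id not in model.reactions:
        raise KeyError(f"no such ATP synthase reaction: {atp_synthase_id!r}")
    if fixation <= 0:
        raise ValueError("fixation value must be positive")
    atps = model.reactions[atp_synthase_id]
    if atps.upper_bound < fixation or atps.lower_bound > fixation:
        raise ValueError(
            f"contradictory fixation: {atp_synthase_id} bounds {atps.bounds} "
            f"cannot hold flux {fixation}"
        )
    with _temporary_bounds(model):
        for rxn in model.exchanges():
            rxn.bounds = (0.0, 0.0)
        atps.bounds = (fixation, fixation)
        state = solve_pfba(model)
    if not state.optimal:
        return LoopReport(False, set(), fixation)
    loop = {
        rid
        for rid, v in state.fluxes.items()
        if abs(v) > LOOP_FLUX_TOL and rid != atp_synthase_id
    }
    return LoopReport(True, loop, fixation)


def check_atp_from_nothing(
    model: MetabolicModel,
    atp_maintenance_id: str,
    max_bound: float = 1000.0,
) -> dict[str, float]:
    """Maximum ATP hydrolysis with no carbon source.

    Closes the uptake of every carbon-bearing exchange metabolite and
    maximizes the maintenance flux, once with photon uptake closed
    (anything positive indicates an energy-generating loop) and once
    with photon open (positive flux is expected photophosphorylation).
    Returns ``{"photon_closed": flux, "photon_open": flux}``.
    """
    if atp_maintenance_id not in model.reactions:
        raise KeyError(f"no such maintenance reaction: {atp_maintenance_id!r}")
    results: dict[str, float] = {}
    for variant, photon_open in (("photon_closed", False), ("photon_open", True)):
        with _temporary_bounds(model):
            for rxn in model.exchanges():
                (met_id,) = rxn.stoichiometry
                met = model.metabolites[met_id]
                stem = (met_id.rsplit("_", 1)[0] if "_" in met_id else met_id).lower()
                carbonaceous = bool(met.formula) and met.formula.get("C", 0) > 0
                if carbonaceous or (stem == "photon" and not photon_open):
                    rxn.bounds = (0.0, rxn.upper_bound)
            model.reactions[atp_maintenance_id].bounds = (0.0, max_bound)
            state = solve_fba(model, ObjectiveSpec.maximize(atp_maintenance_id))
        results[variant] = state.objective_value if state.optimal else 0.0
    return results


def record_evidence(
    model: MetabolicModel, reaction_id: str, evidence_tag: str
) -> MetabolicModel:
    """Tag a reaction's support level (annotated / gap_filled / orphan)."""
    if evidence_tag not in EVIDENCE_TAGS:
        raise ValueError(
            f"unknown evidence tag {evidence_tag!r}; expected one of {EVIDENCE_TAGS}"
        )
    if reaction_id not in model.reactions:
        raise KeyError(f"no such reaction: {reaction_id!r}")
    model.reactions[reaction_id].evidence = evidence_tag
    return model


def evidence_summary(model: MetabolicModel) -> dict[str, int]:
    counts = {tag: 0 for tag in EVIDENCE_TAGS}
    for rxn in model.reactions.values():
        counts[rxn.evidence] += 1
    return counts


def apply_bounds_patch(model: MetabolicModel, patch_path: str) -> list[str]:
    """Apply a manual directionality patch file.

    TSV columns: reaction_id, lb, ub[, citation].  Used to repair loop
    directionality from curated database evidence.  Returns patched ids.
    """
    patched = []
    with open(patch_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("reaction_id"):
                continue
            parts = line.split("\t")
            rid, lb, ub = parts[0], float(parts[1]), float(parts[2])
            if rid not in model.reactions:
                raise KeyError(f"patch references unknown reaction {rid!r}")
            model.reactions[rid].bounds = (lb, ub)
            patched.append(rid)
    return patched
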