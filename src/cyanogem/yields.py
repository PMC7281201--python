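"""Maximum theoretical product yields under a growth floor.

For each candidate product the corresponding exchange flux is maximized
while biomass synthesis is held at or above a fraction (default 80%) of
the wild-type photoautotrophic optimum; the yield is the product flux
divided by the CO2 uptake flux, in mol product per mol CO2.  Products
missing from the network can be introduced through minimal heterologous
pathways (reaction lists with transport/exchange additions), which are
tagged as gap-filled and removable without trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .fba import ObjectiveSpec, SimulationConstraints, exchange_for, solve_fba
from .model import MetabolicModel, Metabolite, Reaction, reaction_element_balance

log = logging.getLogger(__name__)


@dataclass
class HeterologousPathway:
    """Ordered reaction additions enabling a non-native product."""

    name: str
    reactions: list[Reaction]
    new_metabolites: list[Metabolite] = field(default_factory=list)
    source: str = ""


@dataclass
class YieldResult:
    product: str
    exchange_reaction: str
    objective_flux: float  # v_obj, mmol·(gDCW·h)⁻¹
    carbon_uptake_flux: float  # v_c (CO2 + bicarbonate uptake)
    yield_mol_per_mol: float
    carbon_moles_in_product: int | None
    native: bool
    added_reactions: list[str] = field(default_factory=list)
    growth_floor: float = 0.0
    status: str = "optimal"


def add_heterologous_pathway(
    model: MetabolicModel, pathway: HeterologousPathway
) -> MetabolicModel:
    """Return an extended copy of the model; the original is untouched.

    Added reactions must be elementally balanced whenever all involved
    metabolite formulas are known, and are tagged evidence=gap_filled.
    """
    out = model.copy()
    for met in pathway.new_metabolites:
        if met.id not in out.metabolites:
            out.add_metabolite(met.copy())
    for rxn in pathway.reactions:
        if rxn.id in out.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r} in pathway {pathway.name}")
        new = rxn.copy()
        if new.category == "metabolic":
            new.evidence = "gap_filled"
        out.add_reaction(new)
        if new.category not in ("exchange", "demand", "sink"):
            net = reaction_element_balance(out, new)
            if net is not None and any(abs(v) > 1e-6 for v in net.values()):
                raise ValueError(
                    f"pathway reaction {new.id} is mass-imbalanced: net {net}"
                )
    return out


def _met_stem(met_id: str) -> str:
    return (met_id.rsplit("_", 1)[0] if "_" in met_id else met_id).lower()


def _ensure_product_exchange(
    model: MetabolicModel, product: str
) -> tuple[MetabolicModel, str, list[str]]:
    """Resolve or create the secretion route for a product.

    ``product`` is a metabolite base name (``acu``) or id (``acu_c``).
    Missing transport/exchange reactions are added on a copy and
    recorded.
    """
    rid = exchange_for(model, product)
    if rid is not None:
        return model, rid, []
    # locate an intracellular metabolite with this base name
    candidates = [m for m in model.metabolite_ids if _met_stem(m) == product.lower()]
    if product in model.metabolites:
        candidates = [product]
    if not candidates:
        raise KeyError(
            f"product {product!r} not in the model and no pathway supplied; "
            "use add_heterologous_pathway first"
        )
    met_id = sorted(candidates)[0]
    met = model.metabolites[met_id]
    out = model.copy()
    added = []
    stem = _met_stem(met_id)
    ext_id = f"{stem}_e"
    if ext_id not in out.metabolites:
        out.add_metabolite(
            Metabolite(ext_id, met.name, "extracellular",
                       dict(met.formula) if met.formula else None)
        )
    t_id, x_id = f"T_{stem}", f"EX_{stem}"
    if t_id not in out.reactions:
        out.add_reaction(
            Reaction(t_id, {met_id: -1.0, ext_id: 1.0}, 0.0, 1000.0,
                     subsystem="Transport", category="transport",
                     evidence="gap_filled")
        )
        added.append(t_id)
    if x_id not in out.reactions:
        out.add_reaction(
            Reaction(x_id, {ext_id: -1.0}, 0.0, 1000.0,
                     subsystem="Exchange", category="exchange",
                     evidence="gap_filled")
        )
        added.append(x_id)
    log.info("added secretion route for %s: %s", product, added)
    return out, x_id, added


def _carbon_uptake(model: MetabolicModel, fluxes: dict[str, float]) -> float:
    """CO2 exchange uptake, plus bicarbonate uptake if present (logged)."""
    total = 0.0
    co2_x = exchange_for(model, "co2")
    if co2_x is not None:
        total += max(0.0, -fluxes[co2_x])
    hco3_x = exchange_for(model, "hco3")
    if hco3_x is not None and -fluxes[hco3_x] > 0:
        log.info("bicarbonate uptake %.4g added to carbon denominator", -fluxes[hco3_x])
        total += -fluxes[hco3_x]
    return total


def max_product_yield(
    model: MetabolicModel,
    product: str,
    constraints: SimulationConstraints | None = None,
    growth_fraction: float = 0.8,
    pathway: HeterologousPathway | None = None,
    objective: str | None = None,
) -> YieldResult:
    """Maximum theoretical yield of one product under a growth floor.

    Wild-type maximal growth is computed first under the same medium;
    the product exchange is then maximized subject to
    growth ≥ growth_fraction × wild-type (an inequality, so the floor is
    "at least" the fraction).  Yield = v_obj / v_c per the flux-ratio
    definition, with v_c the inorganic-carbon uptake.
    """
    if not 0 <= growth_fraction <= 1:
        raise ValueError("growth_fraction must lie in [0, 1]")
    work = model
    added: list[str] = []
    if pathway is not None:
        work = add_heterologous_pathway(work, pathway)
        added += [r.id for r in pathway.reactions]
    work, exch_id, route_added = _ensure_product_exchange(work, product)
    added += route_added

    biomass_id = objective or (
        constraints.biomass_reaction if constraints else None
    ) or work.objective
    if biomass_id is None:
        raise ValueError("no biomass objective defined")
    wt = solve_fba(work, ObjectiveSpec.maximize(biomass_id), constraints)
    if not wt.optimal:
        raise RuntimeError(f"wild-type growth LP is {wt.status}")
    floor = growth_fraction * wt.objective_value

    saved = work.reactions[biomass_id].bounds
    try:
        work.reactions[biomass_id].bounds = (floor, saved[1])
        state = solve_fba(work, ObjectiveSpec.maximize(exch_id), constraints)
    finally:
        work.reactions[biomass_id].bounds = saved
    if not state.optimal:
        return YieldResult(product, exch_id, float("nan"), float("nan"),
                           float("nan"), None, not added, added, floor, state.status)

    vobj = state.objective_value
    vc = _carbon_uptake(work, state.fluxes)
    yld = vobj / vc if vc > 0 else 0.0
    (ext_met,) = work.reactions[exch_id].stoichiometry
    formula = work.metabolites[ext_met].formula or {}
    n_c = int(formula.get("C", 0)) if formula else None
    return YieldResult(
        product=product,
        exchange_reaction=exch_id,
        objective_flux=vobj,
        carbon_uptake_flux=vc,
        yield_mol_per_mol=yld,
        carbon_moles_in_product=n_c,
        native=not added or all(a.startswith(("T_", "EX_")) for a in added),
        added_reactions=added,
        growth_floor=floor,
    )


def yield_panel(
    model: MetabolicModel,
    products: list[str | tuple[str, HeterologousPathway | None]],
    constraints: SimulationConstraints | None = None,
    growth_fraction: float = 0.8,
) -> pd.DataFrame:
    """Yield table over a product panel, sorted by yield (descending).

    Products are base names, optionally paired with a heterologous
    pathway.  Per-product failures are recorded and the panel continues.
    """
    results: list[YieldResult] = []
    for item in products:
        name, pathway = item if isinstance(item, tuple) else (item, None)
        try:
            results.append(
                max_product_yield(model, name, constraints, growth_fraction, pathway)
            )
        except Exception as exc:  # record and continue
            log.warning("yield computation failed for %s: %s", name, exc)
            results.append(
                YieldResult(name, "", float("nan"), float("nan"), float("nan"),
                            None, False, [], 0.0, f"error: {exc}")
            )
    frame = pd.DataFrame(
        {
            "product": r.product,
            "native": r.native,
            "v_obj": r.objective_flux,
            "v_c": r.carbon_uptake_flux,
            "yield_mol_per_mol": r.yield_mol_per_mol,
            "carbon_moles": r.carbon_moles_in_product,
            "added_reactions": ";".join(r.added_reactions),
            "status": r.status,
        }
        for r in results
    )
    return frame.sort_values(
        "yield_mol_per_mol", ascending=False, na_position="last"
    ).reset_index(drop=True)


def ethanol_pathway() -> HeterologousPathway:
    """Minimal two-step ethanol route: pyruvate decarboxylase + ADH."""
    return HeterologousPathway(
        name="ethanol",
        new_metabolites=[
            Metabolite("acald_c", "acetaldehyde", "cytosol", {"C": 2, "H": 4, "O": 1}),
            Metabolite("etoh_c", "ethanol", "cytosol", {"C": 2, "H": 6, "O": 1}),
        ],
        reactions=[
            Reaction("PDC", {"pyr_c": -1.0, "acald_c": 1.0, "co2_c": 1.0},
                     0.0, 1000.0, subsystem="Heterologous", gene_association="pdc"),
            Reaction("ADH", {"acald_c": -1.0, "nadph_c": -1.0,
                             "etoh_c": 1.0, "nadp_c": 1.0},
                     0.0, 1000.0, subsystem="Heterologous", gene_association="adhB"),
        ],
        source="pyruvate fermentation route",
    )
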