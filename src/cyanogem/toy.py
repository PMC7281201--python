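"""Synthetic photoautotroph models with analytically known ground truth.

The generated network mirrors the motifs of a cyanobacterial
reconstruction at toy scale: lumped linear and cyclic photosynthetic
electron flow producing NADPH and a proton-motive pseudo-metabolite,
ATP synthase, RuBisCO-like CO2 fixation to triose phosphate, an
optional glycogen branch, lower glycolysis, an incomplete TCA cycle
with the 2-oxoglutarate → succinic semialdehyde → succinate shunt,
nitrate assimilation through GS-GOGAT, lumped fatty-acid synthesis,
and a composition-derived biomass equation.  All internal reactions
are elementally balanced (photons and the proton-motive quantum are
massless) and stoichiometries are simple integers, so the unique
minimal flux route — and hence maximal growth, the parsimonious flux
map and the essential set — is derivable in closed form at generation
time.

Light stoichiometry follows the canonical Z-scheme: 8 photons split
2 H2O into one O2, reducing 2 NADP⁺ and translocating enough protons
for 3 ATP; cyclic electron flow adds 1 ATP per 2 photons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biomass import (
    BiomassComposition,
    EnergyParameters,
    Monomer,
    compose_biomass_reaction,
)
from .model import MetabolicModel, Metabolite, Reaction, parse_formula

SUPPORT_TOL = 1e-9


def toy_composition() -> BiomassComposition:
    """Three-component biomass mix with realistic mass-fraction magnitudes.

    Protein-like carbon is represented by glutamyl residues, storage
    carbon by glucosyl units and lipid-like carbon by palmitate;
    fractions follow the measured protein/carbohydrate/lipid pattern of
    a glycogen-rich marine cyanobacterium.
    """
    return BiomassComposition(
        mass_fractions={"protein_like": 0.41, "glycogen": 0.52, "lipid_like": 0.037},
        monomer_profiles={
            "protein_like": [Monomer("glutamyl", 1.0, parse_formula("C5H7NO3"))],
            "glycogen": [Monomer("glucosyl", 1.0, parse_formula("C6H10O5"))],
            "lipid_like": [Monomer("palmitoyl", 1.0, parse_formula("C16H32O2"))],
        },
    )


@dataclass
class ToyModelSpec:
    photon_bound: float = 60.0  # mmol photons ·(gDCW·h)⁻¹ uptake cap
    photons_per_o2: int = 8  # quantum demand of linear electron flow
    include_glycogen_branch: bool = True
    include_tca_shunt: bool = True
    include_gs_gogat: bool = True
    composition: BiomassComposition = field(default_factory=toy_composition)
    energy: EnergyParameters = field(default_factory=EnergyParameters)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_bound <= 0:
            raise ValueError("photon_bound must be positive")
        if (
            not self.include_glycogen_branch
            and self.composition.mass_fractions.get("glycogen", 0) > 0
        ):
            raise ValueError(
                "composition contains glycogen but the glycogen branch is disabled"
            )


@dataclass
class GroundTruth:
    """Analytic reference values shipped with each generated model."""

    max_growth: float
    pfba_fluxes: dict[str, float]  # at growth fixed to max_growth
    essential: set[str]
    nadph_demand: float  # mmol NADPH per unit biomass
    atp_demand: float  # mmol ATP per unit biomass (incl. GAM)
    injected_gaps: list[str] = field(default_factory=list)
    injected_loop: list[str] = field(default_factory=list)


_FORMULAS = {
    "photon": "",
    "pmf": "",
    "co2": "CO2",
    "o2": "O2",
    "h2o": "H2O",
    "hno3": "HNO3",
    "pi": "H3O4P",
    "nh3": "NH3",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "nadp": "C21H28N7O17P3",
    "nadph": "C21H30N7O17P3",
    "g3p": "C3H7O6P",
    "g6p": "C6H13O9P",
    "glucan": "C6H10O5",
    "pyr": "C3H4O3",
    "acu": "C2H4O2",
    "akg": "C5H6O5",
    "glu": "C5H9NO4",
    "gln": "C5H10N2O3",
    "palm": "C16H32O2",
    "ssa": "C4H6O3",
    "succ": "C4H6O4",
}


def generate_toy_photoautotroph(
    spec: ToyModelSpec | None = None,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy model and solve its ground truth in closed form."""
    spec = spec or ToyModelSpec()
    model = MetabolicModel("toy_photoautotroph")
    model.compartments = {
        "extracellular": "extracellular",
        "cytosol": "cytosol",
        "thylakoid": "thylakoid",
    }

    def met(base: str, comp: str) -> str:
        suffix = {"extracellular": "e", "cytosol": "c", "thylakoid": "u"}[comp]
        mid = f"{base}_{suffix}"
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(
                    id=mid,
                    name=base,
                    compartment=comp,
                    formula=parse_formula(_FORMULAS[base]) if base in _FORMULAS else None,
                )
            )
        return mid

    def rxn(rid, stoich, lb, ub, subsystem, category="metabolic", gpr=""):
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=subsystem,
                category=category,
                gene_association=gpr,
            )
        )

    # exchanges: met_e --> nothing; negative flux = uptake
    for base, (lb, ub) in {
        "photon": (-spec.photon_bound, 0.0),
        "co2": (-1000.0, 1000.0),
        "o2": (-1000.0, 1000.0),
        "hno3": (-1000.0, 1000.0),
        "pi": (-1000.0, 1000.0),
        "h2o": (-1000.0, 1000.0),
    }.items():
        rxn(f"EX_{base}", {met(base, "extracellular"): -1.0}, lb, ub, "Exchange", "exchange")

    # transport
    rxn("T_photon", {met("photon", "extracellular"): -1, met("photon", "thylakoid"): 1},
        0, 1000, "Transport", "transport")
    rxn("T_co2", {met("co2", "extracellular"): -1, met("co2", "cytosol"): 1},
        -1000, 1000, "Transport", "transport", gpr="g_tco2")
    rxn("T_o2", {met("o2", "cytosol"): -1, met("o2", "extracellular"): 1},
        -1000, 1000, "Transport", "transport")
    rxn("T_hno3", {met("hno3", "extracellular"): -1, met("hno3", "cytosol"): 1},
        0, 1000, "Transport", "transport", gpr="g_nrt")
    rxn("T_pi", {met("pi", "extracellular"): -1, met("pi", "cytosol"): 1},
        -1000, 1000, "Transport", "transport")
    rxn("T_h2o", {met("h2o", "extracellular"): -1, met("h2o", "cytosol"): 1},
        -1000, 1000, "Transport", "transport")

    # photosynthetic electron flow (thylakoid) -------------------------
    ppo = spec.photons_per_o2
    rxn("PSET",
        {met("h2o", "cytosol"): -2, met("photon", "thylakoid"): -ppo,
         met("nadp", "cytosol"): -2, met("o2", "cytosol"): 1,
         met("nadph", "cytosol"): 2, met("pmf", "thylakoid"): 9},
        0, 1000, "Photosynthesis", gpr="g_psii and g_psi")
    rxn("CEF",
        {met("photon", "thylakoid"): -2, met("pmf", "thylakoid"): 3},
        0, 1000, "Photosynthesis", gpr="g_psi")
    rxn("ATPS",
        {met("pmf", "thylakoid"): -3, met("adp", "cytosol"): -1,
         met("pi", "cytosol"): -1, met("atp", "cytosol"): 1,
         met("h2o", "cytosol"): 1},
        0, 1000, "Photosynthesis", gpr="g_atps")

    # carbon fixation and central carbon metabolism --------------------
    rxn("CBB",
        {met("co2", "cytosol"): -3, met("nadph", "cytosol"): -6,
         met("atp", "cytosol"): -9, met("h2o", "cytosol"): -5,
         met("g3p", "cytosol"): 1, met("nadp", "cytosol"): 6,
         met("adp", "cytosol"): 9, met("pi", "cytosol"): 8},
        0, 1000, "Calvin cycle", gpr="g_rbc and g_prk")
    rxn("GLYC",
        {met("g3p", "cytosol"): -1, met("pi", "cytosol"): -1,
         met("nadp", "cytosol"): -1, met("adp", "cytosol"): -2,
         met("pyr", "cytosol"): 1, met("nadph", "cytosol"): 1,
         met("atp", "cytosol"): 2, met("h2o", "cytosol"): 1},
        0, 1000, "Glycolysis", gpr="g_gap and g_pyk")
    rxn("PDH",
        {met("pyr", "cytosol"): -1, met("h2o", "cytosol"): -1,
         met("nadp", "cytosol"): -1, met("acu", "cytosol"): 1,
         met("co2", "cytosol"): 1, met("nadph", "cytosol"): 1},
        0, 1000, "TCA cycle", gpr="g_pdh")
    rxn("AKGS",
        {met("pyr", "cytosol"): -2, met("h2o", "cytosol"): -1,
         met("nadp", "cytosol"): -2, met("akg", "cytosol"): 1,
         met("co2", "cytosol"): 1, met("nadph", "cytosol"): 2},
        0, 1000, "TCA cycle", gpr="g_cs and g_icd")

    if spec.include_glycogen_branch:
        rxn("PGI",
            {met("g3p", "cytosol"): -2, met("h2o", "cytosol"): -1,
             met("g6p", "cytosol"): 1, met("pi", "cytosol"): 1},
            0, 1000, "Carbohydrate metabolism", gpr="g_fbp and g_pgi")
        rxn("GLGS",
            {met("g6p", "cytosol"): -1, met("atp", "cytosol"): -1,
             met("h2o", "cytosol"): -1, met("glucan", "cytosol"): 1,
             met("adp", "cytosol"): 1, met("pi", "cytosol"): 2},
            0, 1000, "Carbohydrate metabolism", gpr="g_glgc and g_glga")

    if spec.include_tca_shunt:
        rxn("OGDC",
            {met("akg", "cytosol"): -1, met("ssa", "cytosol"): 1,
             met("co2", "cytosol"): 1},
            0, 1000, "TCA cycle")  # orphan in cyanobacteria
        model.reactions["OGDC"].evidence = "orphan"
        rxn("SSADH",
            {met("ssa", "cytosol"): -1, met("h2o", "cytosol"): -1,
             met("nadp", "cytosol"): -1, met("succ", "cytosol"): 1,
             met("nadph", "cytosol"): 1},
            0, 1000, "TCA cycle", gpr="g_ssadh")
        rxn("T_succ", {met("succ", "cytosol"): -1, met("succ", "extracellular"): 1},
            0, 1000, "Transport", "transport")
        rxn("EX_succ", {met("succ", "extracellular"): -1}, 0, 1000,
            "Exchange", "exchange")

    # nitrogen assimilation -------------------------------------------
    rxn("NIR",
        {met("hno3", "cytosol"): -1, met("nadph", "cytosol"): -4,
         met("nh3", "cytosol"): 1, met("nadp", "cytosol"): 4,
         met("h2o", "cytosol"): 3},
        0, 1000, "Nitrogen metabolism", gpr="g_nar and g_nir")
    if spec.include_gs_gogat:
        rxn("GS",
            {met("glu", "cytosol"): -1, met("nh3", "cytosol"): -1,
             met("atp", "cytosol"): -1, met("gln", "cytosol"): 1,
             met("adp", "cytosol"): 1, met("pi", "cytosol"): 1},
            0, 1000, "Nitrogen metabolism", gpr="g_glna")
        rxn("GOGAT",
            {met("gln", "cytosol"): -1, met("akg", "cytosol"): -1,
             met("nadph", "cytosol"): -1, met("glu", "cytosol"): 2,
             met("nadp", "cytosol"): 1},
            0, 1000, "Nitrogen metabolism", gpr="g_gltb")
    else:
        rxn("GDH",
            {met("akg", "cytosol"): -1, met("nh3", "cytosol"): -1,
             met("nadph", "cytosol"): -1, met("glu", "cytosol"): 1,
             met("nadp", "cytosol"): 1, met("h2o", "cytosol"): 1},
            0, 1000, "Nitrogen metabolism", gpr="g_gdh")

    # lumped fatty-acid synthesis -------------------------------------
    rxn("FAS",
        {met("acu", "cytosol"): -8, met("nadph", "cytosol"): -14,
         met("atp", "cytosol"): -7, met("palm", "cytosol"): 1,
         met("nadp", "cytosol"): 14, met("adp", "cytosol"): 7,
         met("pi", "cytosol"): 7, met("h2o", "cytosol"): 7},
        0, 1000, "Fatty acid metabolism", gpr="g_fab")

    # acetate secretion route (native product) ------------------------
    rxn("T_ac", {met("acu", "cytosol"): -1, met("acu", "extracellular"): 1},
        0, 1000, "Transport", "transport")
    rxn("EX_ac", {met("acu", "extracellular"): -1}, 0, 1000, "Exchange", "exchange")

    # biomass and maintenance -----------------------------------------
    model.add_metabolite(Metabolite("biomass_c", "biomass", "cytosol"))
    eq = compose_biomass_reaction(
        spec.composition,
        spec.energy,
        metabolite_map={
            "glutamyl": "glu_c",
            "glucosyl": "glucan_c",
            "palmitoyl": "palm_c",
        },
        reaction_id="BIOMASS",
        biomass_metabolite="biomass_c",
    )
    model.add_reaction(eq.reaction)
    rxn("SK_biomass", {"biomass_c": -1.0}, 0, 1000, "Biomass", "sink")
    rxn("ATPM",
        {met("atp", "cytosol"): -1, met("h2o", "cytosol"): -1,
         met("adp", "cytosol"): 1, met("pi", "cytosol"): 1},
        0, 1000, "Maintenance", "maintenance")
    model.objective = "BIOMASS"
    model.objective_direction = "max"

    truth = _closed_form_truth(model, spec, eq.precursor_coefficients)
    return model, truth


def _closed_form_truth(
    model: MetabolicModel, spec: ToyModelSpec, precursors: dict[str, float]
) -> GroundTruth:
    """Hand-derived route accounting for the tree-shaped toy network.

    Every internal flux is forced by the biomass demands; linear
    electron flow is set by the NADPH balance, cyclic flow closes the
    ATP balance, and the photon bound caps growth:
    μ_max = (photon_bound − 2·NGAM) / (D_NADPH + 2·D_ATP).
    """
    glu_n = precursors.get("glu_c", 0.0)
    glucan_n = precursors.get("glucan_c", 0.0)
    palm_n = precursors.get("palm_c", 0.0)
    gam, ngam = spec.energy.gam, spec.energy.ngam

    pyr_n = 2 * glu_n + 8 * palm_n  # AKGS needs 2 pyr per 2-OG; FAS 8 acetyl
    g3p_n = 2 * glucan_n + pyr_n
    cbb = g3p_n

    # per-unit-biomass NADPH: consumers minus internal producers
    d_nadph = (
        6 * cbb
        + 4 * glu_n  # nitrate reduction
        + (1 * glu_n if spec.include_gs_gogat else 1 * glu_n)  # GOGAT / GDH
        + 14 * palm_n
        - 1 * pyr_n  # GLYC (only trioses continuing past the glycogen branch)
        - 8 * palm_n  # PDH
        - 2 * glu_n  # AKGS
    )
    # per-unit-biomass ATP: consumers minus substrate-level production
    d_atp = (
        9 * cbb
        + glucan_n  # GLGS
        + (glu_n if spec.include_gs_gogat else 0.0)  # GS
        + 7 * palm_n
        + gam
        - 2 * pyr_n  # GLYC
    )
    if d_nadph <= 0 or d_atp <= 0:
        raise ValueError("degenerate toy composition: non-positive energy demand")

    mu = (spec.photon_bound - 2 * ngam) / (d_nadph + 2 * d_atp)
    if mu <= 0:
        raise ValueError("photon bound too small to sustain maintenance")

    def fluxes_at(mu: float) -> dict[str, float]:
        pset = d_nadph * mu / 2
        atps = d_atp * mu + ngam
        cef = (3 * atps - 9 * pset) / 3
        if cef < -SUPPORT_TOL:
            raise ValueError("toy composition implies negative cyclic electron flow")
        v = {rid: 0.0 for rid in model.reaction_ids}
        v["BIOMASS"] = mu
        v["SK_biomass"] = mu
        v["ATPM"] = ngam
        v["PSET"] = pset
        v["CEF"] = max(cef, 0.0)
        v["ATPS"] = atps
        v["CBB"] = cbb * mu
        v["GLYC"] = g3p_n * mu - 2 * glucan_n * mu
        if spec.include_glycogen_branch:
            v["PGI"] = glucan_n * mu
            v["GLGS"] = glucan_n * mu
        v["PDH"] = 8 * palm_n * mu
        v["AKGS"] = glu_n * mu
        v["NIR"] = glu_n * mu
        if spec.include_gs_gogat:
            v["GS"] = glu_n * mu
            v["GOGAT"] = glu_n * mu
        else:
            v["GDH"] = glu_n * mu
        v["FAS"] = palm_n * mu
        # exchange and transport fluxes from per-metabolite balances
        co2_uptake = 3 * cbb * mu - v["PDH"] - v["AKGS"]
        v["T_co2"] = co2_uptake
        v["EX_co2"] = -co2_uptake
        v["T_photon"] = spec.photons_per_o2 * pset + 2 * v["CEF"]
        v["EX_photon"] = -v["T_photon"]
        v["T_o2"] = pset
        v["EX_o2"] = pset
        v["T_hno3"] = glu_n * mu
        v["EX_hno3"] = -glu_n * mu
        # water: producers minus consumers in the cytosol
        h2o_net = (
            v["ATPS"]
            + v["GLYC"]
            + 3 * v["NIR"]
            + 7 * v["FAS"]
            - 2 * v["PSET"]
            - 5 * v["CBB"]
            - v["PDH"]
            - v["AKGS"]
            - v["ATPM"]
            - gam * mu
            - (v.get("PGI", 0.0) + v.get("GLGS", 0.0))
            + (v["GDH"] if not spec.include_gs_gogat else 0.0)
        )
        v["T_h2o"] = -h2o_net
        v["EX_h2o"] = h2o_net
        return v

    fluxes = fluxes_at(mu)
    # every route reaction is essential (the network has no redundant
    # paths) except the maintenance drain: its deletion removes the NGAM
    # demand with it under the knockout convention
    essential = {
        rid
        for rid, x in fluxes.items()
        if abs(x) > SUPPORT_TOL and model.reactions[rid].category != "maintenance"
    }
    return GroundTruth(
        max_growth=mu,
        pfba_fluxes=fluxes,
        essential=essential,
        nadph_demand=d_nadph,
        atp_demand=d_atp,
    )


PROTECTED_CATEGORIES = ("exchange", "biomass", "sink", "maintenance")


def inject_gaps(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    count: int | None = None,
    seed: int = 0,
) -> tuple[MetabolicModel, list[str]]:
    """Remove internal reactions to create known biosynthetic gaps.

    Either an explicit id list or a seeded random draw of ``count``
    internal reactions.  Exchange, biomass, sink and maintenance
    reactions may not be removed.  Returns a modified copy and the
    removal list (the ground truth for gap finding).
    """
    out = model.copy()
    if reaction_ids is None:
        if count is None:
            return out, []
        rng = np.random.default_rng(seed)
        pool = [
            rid
            for rid in out.reaction_ids
            if out.reactions[rid].category not in PROTECTED_CATEGORIES
        ]
        reaction_ids = sorted(rng.choice(pool, size=count, replace=False).tolist())
    removed = []
    for rid in reaction_ids:
        if rid not in out.reactions:
            raise KeyError(f"cannot remove unknown reaction {rid!r}")
        if out.reactions[rid].category in PROTECTED_CATEGORIES:
            raise ValueError(f"refusing to remove protected reaction {rid!r}")
        out.remove_reaction(rid)
        removed.append(rid)
    return out, removed


def inject_loop(model: MetabolicModel) -> tuple[MetabolicModel, list[str]]:
    """Add a thermodynamically infeasible energy-generating cycle.

    Two mass-balanced reactions interconvert a metabolite pair while
    emitting proton-motive quanta from nothing, allowing ATP synthesis
    with all exchanges closed — the signature the loop detector and the
    ATP-from-nothing test look for.
    """
    out = model.copy()
    if "pmf_u" not in out.metabolites:
        raise ValueError("model lacks the proton-motive metabolite pmf_u")
    out.add_metabolite(
        Metabolite("loopA_c", "loop metabolite A", "cytosol", parse_formula("C4H8O4"))
    )
    out.add_metabolite(
        Metabolite("loopB_c", "loop metabolite B", "cytosol", parse_formula("C4H8O4"))
    )
    out.add_reaction(
        Reaction(
            id="LOOP1",
            stoichiometry={"loopA_c": -1.0, "loopB_c": 1.0, "pmf_u": 3.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Artifact",
            category="metabolic",
            evidence="gap_filled",
        )
    )
    out.add_reaction(
        Reaction(
            id="LOOP2",
            stoichiometry={"loopB_c": -1.0, "loopA_c": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Artifact",
            category="metabolic",
            evidence="gap_filled",
        )
    )
    return out, ["LOOP1", "LOOP2"]
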