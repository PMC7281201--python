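"""Biomass equation construction from macromolecular composition.

Measured mass fractions (mg component per mg dry cell weight) are turned
into mmol·gDCW⁻¹ precursor coefficients via monomer templates: for a
polymeric component with mass fraction *w* and monomer mole fractions
*x_m* over residues of molar mass *M_m*, monomer *m* receives the
coefficient ``1000 · w · x_m / M̄`` with ``M̄ = Σ x_m M_m`` the
mole-fraction-weighted residue mass.  From the coefficients the module
derives the per-carbon elemental biomass formula CH_aO_bN_c… and its
degree of reduction γ (available electrons per C-mol relative to CO2,
H2O and a declared nitrogen reference), plus the photosynthetic-quotient
estimate of O2 evolution, γ/4 · (CO2 uptake).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .model import Reaction, format_formula, parse_formula

log = logging.getLogger(__name__)

ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Mg": 24.305,
    "Fe": 55.845,
    "K": 39.098,
    "Na": 22.990,
    "Ca": 40.078,
    "Cl": 35.45,
}

#: degree-of-reduction weights relative to CO2 / H2O and mineral cations
REDUCTION_WEIGHTS = {
    "C": 4.0,
    "H": 1.0,
    "O": -2.0,
    "P": 5.0,
    "S": 6.0,
    "Mg": 2.0,
    "K": 1.0,
    "Na": 1.0,
    "Ca": 2.0,
    "Fe": 3.0,
    "Cl": -1.0,
}

#: electrons per N under the two common nitrogen reference states
N_REFERENCE_WEIGHTS = {"NH3": -3.0, "NO3": 5.0}

CLOSURE_TOLERANCE = 0.05  # |sum of mass fractions - 1| triggering a warning


def molar_mass(formula: dict[str, float]) -> float:
    try:
        return sum(ATOMIC_MASS[e] * n for e, n in formula.items())
    except KeyError as exc:
        raise ValueError(f"no atomic mass for element {exc}") from exc


@dataclass
class Monomer:
    id: str
    mole_fraction: float
    formula: dict[str, float]

    @property
    def residue_mass(self) -> float:
        return molar_mass(self.formula)


def load_monomer_templates(path: str | None = None) -> dict[str, list[Monomer]]:
    """Load component → monomer-profile templates from YAML.

    ``None`` loads the packaged defaults.  A component may alias another
    by mapping to its name instead of a list.  Profiles are normalized to
    sum to exactly 1.
    """
    if path is None:
        text = (
            resources.files("cyanogem.data")
            .joinpath("monomer_templates.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, list[Monomer]] = {}
    aliases: dict[str, str] = {}
    for comp, entries in raw.items():
        if isinstance(entries, str):
            aliases[comp] = entries
            continue
        monomers = [
            Monomer(
                id=e["id"],
                mole_fraction=float(e["mole_fraction"]),
                formula=parse_formula(e["formula"])
                if isinstance(e["formula"], str)
                else dict(e["formula"]),
            )
            for e in entries
        ]
        total = sum(m.mole_fraction for m in monomers)
        if abs(total - 1.0) > 0.02:
            raise ValueError(f"monomer profile for {comp!r} sums to {total:.4f}")
        for m in monomers:
            m.mole_fraction /= total
        out[comp] = monomers
    for comp, target in aliases.items():
        if target not in out:
            raise ValueError(f"template alias {comp!r} -> unknown {target!r}")
        out[comp] = out[target]
    return out


@dataclass
class BiomassComposition:
    """Measured mass fractions (mg/mg DCW) plus monomer profiles."""

    mass_fractions: dict[str, float]
    monomer_profiles: dict[str, list[Monomer]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp, w in self.mass_fractions.items():
            if w < 0:
                raise ValueError(f"negative mass fraction for {comp!r}: {w}")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > CLOSURE_TOLERANCE:
            warnings.warn(
                f"mass fractions sum to {total:.4f}; "
                f"|sum-1| exceeds the closure tolerance {CLOSURE_TOLERANCE}",
                stacklevel=2,
            )

    @classmethod
    def from_csv(
        cls, path, templates: dict[str, list[Monomer]] | None = None
    ) -> "BiomassComposition":
        """Read a ``component,mass_fraction_mg_per_mg[,sd]`` CSV."""
        fractions: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                fractions[row["component"].strip()] = float(
                    row["mass_fraction_mg_per_mg"]
                )
        return cls(fractions, templates or load_monomer_templates())

    @classmethod
    def bdu130192(cls) -> "BiomassComposition":
        """The measured composition of *Synechococcus* sp. BDU 130192.

        Total carbohydrate is split into its glycogen and non-glycogen
        parts so glucosyl units from storage and structural pools can be
        mapped to distinct precursors.
        """
        with resources.as_file(
            resources.files("cyanogem.data").joinpath("bdu130192_composition.csv")
        ) as p:
            return cls.from_csv(p)


def normalize_composition(composition: BiomassComposition) -> dict[str, float]:
    """Precursor coefficients in mmol per gDCW.

    Components with zero mass fraction are omitted.  Monomers shared by
    several components accumulate.
    """
    coeffs: dict[str, float] = {}
    for comp, w in composition.mass_fractions.items():
        if w == 0:
            continue
        if comp not in composition.monomer_profiles:
            raise ValueError(f"no monomer template for component {comp!r}")
        profile = composition.monomer_profiles[comp]
        mean_mass = sum(m.mole_fraction * m.residue_mass for m in profile)
        if mean_mass <= 0:
            raise ValueError(f"component {comp!r} has zero mean residue mass")
        for m in profile:
            if m.mole_fraction == 0:
                continue
            coeffs[m.id] = coeffs.get(m.id, 0.0) + 1000.0 * w * m.mole_fraction / mean_mass
    return coeffs


def monomer_formulas(composition: BiomassComposition) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for profile in composition.monomer_profiles.values():
        for m in profile:
            out.setdefault(m.id, m.formula)
    return out


@dataclass
class EnergyParameters:
    """Growth- and non-growth-associated ATP maintenance.

    gam: mmol ATP·gDCW⁻¹ charged in the biomass equation.
    ngam: mmol ATP·(gDCW·h)⁻¹ fixed through a separate hydrolysis reaction.
    Defaults are the values commonly adopted for marine *Synechococcus*
    models; both are scan parameters, not measurements for this strain.
    """

    gam: float = 53.0
    ngam: float = 1.3
    provenance: str = "adopted from PCC 7002 genome-scale models"

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be non-negative")


@dataclass
class BiomassEquation:
    precursor_coefficients: dict[str, float]
    gam_atp: float
    reaction: Reaction

    def mass_closure(self, formulas: dict[str, dict[str, float]]) -> float:
        """Σ coefficient × residue molar mass, in mg per gDCW (target 1000)."""
        return sum(
            c * molar_mass(formulas[m])
            for m, c in self.precursor_coefficients.items()
        )


def compose_biomass_reaction(
    composition: BiomassComposition,
    energy: EnergyParameters,
    metabolite_map: dict[str, str] | None = None,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str | None = "biomass_c",
    energy_metabolites: dict[str, str] | None = None,
) -> BiomassEquation:
    """Assemble the biomass pseudo-reaction.

    Consumes each precursor at its mmol/gDCW coefficient plus ``gam`` ATP
    and water, produces one unit of biomass plus ``gam`` ADP and
    phosphate.  ``metabolite_map`` renames monomer ids to model
    metabolite ids (default: identity).
    """
    metabolite_map = metabolite_map or {}
    em = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c"}
    em.update(energy_metabolites or {})
    coeffs = normalize_composition(composition)
    stoich: dict[str, float] = {}
    mapped: dict[str, float] = {}
    for mono, c in coeffs.items():
        met = metabolite_map.get(mono, mono)
        stoich[met] = stoich.get(met, 0.0) - c
        mapped[met] = mapped.get(met, 0.0) + c
    gam = energy.gam
    if gam > 0:
        stoich[em["atp"]] = stoich.get(em["atp"], 0.0) - gam
        stoich[em["h2o"]] = stoich.get(em["h2o"], 0.0) - gam
        stoich[em["adp"]] = stoich.get(em["adp"], 0.0) + gam
        stoich[em["pi"]] = stoich.get(em["pi"], 0.0) + gam
    if biomass_metabolite is not None:
        stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    rxn = Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="Biomass synthesis",
        subsystem="Biomass",
        category="biomass",
    )
    return BiomassEquation(mapped, gam, rxn)


@dataclass
class ElementalFormula:
    """Per-carbon biomass formula CH_aO_bN_c… (C normalized to 1)."""

    per_carbon: dict[str, float]
    total_carbon_mmol: float

    def __str__(self) -> str:
        return format_formula(
            {e: round(n, 4) for e, n in self.per_carbon.items()}
        )


def elemental_formula(
    coefficients: dict[str, float],
    formulas: dict[str, dict[str, float]],
) -> ElementalFormula:
    """Per-carbon elemental composition of the biomass precursors.

    Energy/bookkeeping species must already be excluded — pass the
    ``precursor_coefficients`` of a :class:`BiomassEquation`.
    """
    totals: dict[str, float] = {}
    for met, coef in coefficients.items():
        if met not in formulas:
            raise ValueError(f"no elemental formula for precursor {met!r}")
        for e, n in formulas[met].items():
            totals[e] = totals.get(e, 0.0) + coef * n
    c = totals.get("C", 0.0)
    if c <= 0:
        raise ValueError("biomass contains no carbon; cannot normalize")
    return ElementalFormula({e: n / c for e, n in totals.items()}, c)


def degree_of_reduction(
    formula: ElementalFormula | dict[str, float],
    n_reference: str = "NH3",
    weights: dict[str, float] | None = None,
) -> float:
    """γ = Σ weight_e × count_e over the per-carbon formula.

    Reference states: CO2, H2O, and NH3 (weight −3) or NO3⁻ (weight +5)
    for nitrogen.  γ(CH2O) = 4, γ(CO2) = 0.
    """
    counts = formula.per_carbon if isinstance(formula, ElementalFormula) else formula
    w = dict(REDUCTION_WEIGHTS)
    if n_reference not in N_REFERENCE_WEIGHTS:
        raise ValueError(f"unknown N reference {n_reference!r}; use NH3 or NO3")
    w["N"] = N_REFERENCE_WEIGHTS[n_reference]
    if weights:
        w.update(weights)
    missing = [e for e in counts if e not in w]
    if missing:
        raise ValueError(f"no reduction weight for element(s) {missing}")
    return sum(w[e] * n for e, n in counts.items())


def photosynthetic_quotient_o2(
    gamma_biomass: float, co2_uptake: float
) -> tuple[float, float]:
    """O2 evolution implied by the photosynthetic quotient γ/4.

    With nitrate as N source the electrons stored per fixed C-mol of
    biomass equal the NO3⁻-referenced γ; four electrons per O2 give
    PQ = γ/4 and an O2 rate of PQ × CO2 uptake.  Returns
    ``(o2_rate, quotient)``.
    """
    if gamma_biomass < 0 or co2_uptake < 0:
        raise ValueError("gamma and CO2 uptake must be non-negative")
    pq = gamma_biomass / 4.0
    return pq * co2_uptake, pq
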