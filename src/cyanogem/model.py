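"""Compartmentalized stoichiometric network model.

The central container mirrors the constraint-based modelling convention:
metabolites carry elemental formulas and compartments, reactions carry
signed stoichiometries (negative = consumed), flux bounds in
mmol·(gDCW·h)⁻¹, a subsystem label, a category tag and an optional
boolean gene association.  The stoichiometric matrix N (metabolites ×
reactions) is built sparse so that N·v gives net metabolite production
for any flux vector v.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

DEFAULT_LB = -1000.0
DEFAULT_UB = 1000.0

REACTION_CATEGORIES = (
    "metabolic",
    "transport",
    "exchange",
    "biomass",
    "maintenance",
    "demand",
    "sink",
)

EVIDENCE_TAGS = ("annotated", "gap_filled", "orphan")

#: categories exempt from elemental balance (boundary / pseudo reactions)
UNBALANCED_CATEGORIES = frozenset(
    {"exchange", "biomass", "demand", "sink", "maintenance"}
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> dict[str, float]:
    """Parse a Hill-style formula string like ``C6H12O6`` into a dict.

    Fractional counts (``CH1.59O0.57``) are accepted, as they occur in
    averaged biomass formulas.
    """
    if not text:
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        n = float(m.group(2)) if m.group(2) else 1.0
        counts[m.group(1)] = counts.get(m.group(1), 0.0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return counts


def format_formula(counts: dict[str, float]) -> str:
    """Render an element→count map as a Hill-ordered formula string."""

    def fmt(x: float) -> str:
        if abs(x - round(x)) < 1e-9:
            return "" if round(x) == 1 else str(int(round(x)))
        return f"{x:g}"

    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{fmt(counts[e])}" for e in order if counts[e] != 0)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: dict[str, float] | None = None
    charge: int | None = None

    def copy(self) -> "Metabolite":
        # an empty formula map means "massless", distinct from unknown (None)
        return replace(
            self, formula=dict(self.formula) if self.formula is not None else None
        )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = DEFAULT_LB
    upper_bound: float = DEFAULT_UB
    name: str = ""
    subsystem: str = ""
    category: str = "metabolic"
    gene_association: str = ""
    evidence: str = "annotated"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.category not in REACTION_CATEGORIES:
            raise ValueError(f"reaction {self.id}: unknown category {self.category!r}")
        if self.evidence not in EVIDENCE_TAGS:
            raise ValueError(f"reaction {self.id}: unknown evidence {self.evidence!r}")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ValueError(f"reaction {self.id}: bounds {value} inverted")
        self.lower_bound, self.upper_bound = float(lb), float(ub)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def equation(self) -> str:
        """Human-readable reaction string, substrates on the left."""
        lhs = [(m, -c) for m, c in sorted(self.stoichiometry.items()) if c < 0]
        rhs = [(m, c) for m, c in sorted(self.stoichiometry.items()) if c > 0]

        def side(terms):
            return " + ".join(
                (f"{c:g} {m}" if abs(c - 1) > 1e-12 else m) for m, c in terms
            )

        arrow = "<=>" if self.reversible else "-->"
        return f"{side(lhs)} {arrow} {side(rhs)}"


class MetabolicModel:
    """A metabolic reconstruction: metabolites, reactions, genes, objective."""

    def __init__(self, model_id: str = "model", name: str = ""):
        self.id = model_id
        self.name = name or model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: set[str] = set()
        self.compartments: dict[str, str] = {}
        self.objective: str | None = None
        self.objective_direction: str = "max"

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id}")
        if met.compartment not in self.compartments:
            self.compartments[met.compartment] = met.compartment
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(f"reaction {rxn.id} references unknown metabolites {missing}")
        self.reactions[rxn.id] = rxn
        self.genes.update(genes_in_association(rxn.gene_association))

    def remove_reaction(self, reaction_id: str) -> Reaction:
        return self.reactions.pop(reaction_id)

    def copy(self) -> "MetabolicModel":
        out = MetabolicModel(self.id, self.name)
        out.compartments = dict(self.compartments)
        for met in self.metabolites.values():
            out.add_metabolite(met.copy())
        for rxn in self.reactions.values():
            out.add_reaction(rxn.copy())
        out.genes = set(self.genes)
        out.objective = self.objective
        out.objective_direction = self.objective_direction
        return out

    # -- queries ------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        """Boundary exchange reactions.

        Uses the category tag when set; otherwise falls back to the
        single-metabolite heuristic common to published reconstructions.
        """
        tagged = [r for r in self.reactions.values() if r.category == "exchange"]
        if tagged:
            return sorted(tagged, key=lambda r: r.id)
        return sorted(
            (
                r
                for r in self.reactions.values()
                if len(r.stoichiometry) == 1
                and r.category not in ("biomass", "demand", "sink", "maintenance")
            ),
            key=lambda r: r.id,
        )

    def summary(self) -> dict:
        cat, sub = count_by_category(self)
        return {
            "id": self.id,
            "genes": len(self.genes),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "compartments": sorted(self.compartments),
            "by_category": cat,
            "by_subsystem": sub,
            "objective": self.objective,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


_GENE_SPLIT = re.compile(r"[()\s]+")


def genes_in_association(expression: str) -> set[str]:
    """Gene ids appearing in a boolean association string like ``(g1 and g2) or g3``."""
    if not expression:
        return set()
    return {
        tok
        for tok in _GENE_SPLIT.split(expression)
        if tok and tok.lower() not in ("and", "or")
    }


def build_matrix(model: MetabolicModel):
    """Sparse stoichiometric matrix N with sorted row/column index lists.

    Returns ``(N, metabolite_ids, reaction_ids)`` where N is CSR of shape
    (#metabolites, #reactions) and column j reproduces reaction j.
    """
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    N = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return N, met_ids, rxn_ids


def reaction_element_balance(
    model: MetabolicModel, reaction: Reaction
) -> dict[str, float] | None:
    """Net atoms produced per element, or None if any formula is missing."""
    net: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        formula = model.metabolites[met_id].formula
        if formula is None:
            return None
        for elem, n in formula.items():
            net[elem] = net.get(elem, 0.0) + coef * n
    return {e: v for e, v in net.items() if abs(v) > 1e-9}


def check_mass_balance(model: MetabolicModel, atol: float = 1e-6):
    """Flag elementally imbalanced reactions.

    Boundary categories (exchange/biomass/demand/sink/maintenance) are
    exempt.  Returns ``(imbalanced, skipped)``: a map reaction id → net
    element counts for violations, and the list of reactions skipped for
    missing formulas.
    """
    imbalanced: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        if rxn.category in UNBALANCED_CATEGORIES:
            continue
        net = reaction_element_balance(model, rxn)
        if net is None:
            skipped.append(rid)
        elif any(abs(v) > atol for v in net.values()):
            imbalanced[rid] = net
    return imbalanced, skipped


def count_by_category(model: MetabolicModel):
    """Reaction counts per category and per subsystem (a partition each)."""
    by_cat: dict[str, int] = {}
    by_sub: dict[str, int] = {}
    for rxn in model.reactions.values():
        by_cat[rxn.category] = by_cat.get(rxn.category, 0) + 1
        sub = rxn.subsystem or "(none)"
        by_sub[sub] = by_sub.get(sub, 0) + 1
    return by_cat, by_sub


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Deep structural equality on model content (ids, stoichiometry, bounds)."""
    if sorted(a.metabolites) != sorted(b.metabolites):
        return False
    if sorted(a.reactions) != sorted(b.reactions):
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        fa = ma.formula or {}
        fb = mb.formula or {}
        if set(fa) != set(fb) or any(abs(fa[e] - fb[e]) > tol for e in fa):
            return False
        if ma.compartment != mb.compartment:
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        if any(
            abs(ra.stoichiometry[m] - rb.stoichiometry[m]) > tol
            for m in ra.stoichiometry
        ):
            return False
        if (
            abs(ra.lower_bound - rb.lower_bound) > tol
            or abs(ra.upper_bound - rb.upper_bound) > tol
        ):
            return False
        if (ra.category, ra.subsystem, ra.gene_association) != (
            rb.category,
            rb.subsystem,
            rb.gene_association,
        ):
            return False
    return a.objective == b.objective and np.isclose(0, 0)
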