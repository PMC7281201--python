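"""SBML read/write for metabolic models.

Writes SBML Level 3 Version 1 with the FBC v2 package (bounds as shared
flux-bound parameters, objective as an FBC objective, gene associations
as FBC gene-product associations).  Reads both FBC-annotated files and
legacy Level 2 files that store bounds as ``LOWER_BOUND``/``UPPER_BOUND``
kinetic-law parameters.  Subsystem, category and evidence tags — which
core SBML has no first-class slot for — travel in reaction notes as
``KEY: value`` lines, the convention used by most published
reconstructions.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .model import (
    DEFAULT_LB,
    DEFAULT_UB,
    EVIDENCE_TAGS,
    REACTION_CATEGORIES,
    MetabolicModel,
    Metabolite,
    Reaction,
    format_formula,
    parse_formula,
)

log = logging.getLogger(__name__)

# SBML SIds must match [a-zA-Z_][a-zA-Z0-9_]*; other characters are
# escaped reversibly as __uXXXX__.
_SID_BAD = re.compile(r"[^A-Za-z0-9_]")
_SID_ESC = re.compile(r"__u([0-9a-fA-F]{4})__")


def _sanitize_id(raw: str) -> str:
    out = _SID_BAD.sub(lambda m: f"__u{ord(m.group(0)):04x}__", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _unsanitize_id(sid: str) -> str:
    out = _SID_ESC.sub(lambda m: chr(int(m.group(1), 16)), sid)
    if out.startswith("_") and len(out) > 1 and not _SID_BAD.search(out[1:]):
        # strip the guard underscore only if it was added by us
        candidate = out[1:]
        if candidate and not (candidate[0].isalpha() or candidate[0] == "_"):
            return candidate
    return out


_NOTE_LINE = re.compile(r"([A-Z_]+)\s*:\s*(.*?)\s*(?:</|$)")


def _notes_dict(sbase) -> dict[str, str]:
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    out = {}
    for line in re.split(r"<p>|\n", text):
        m = _NOTE_LINE.search(line)
        if m:
            out[m.group(1)] = m.group(2)
    return out


def _set_notes(sbase, pairs: dict[str, str]) -> None:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items() if v)
    if not body:
        return
    xhtml = f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    sbase.setNotes(xhtml)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize a model as SBML L3V1 + FBC v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sanitize_id(model.id))
    smodel.setName(model.name)
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in sorted(model.compartments):
        comp = smodel.createCompartment()
        comp.setId(_sanitize_id(cid))
        comp.setName(model.compartments[cid])
        comp.setConstant(True)

    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        sp = smodel.createSpecies()
        sp.setId(_sanitize_id(mid))
        sp.setName(met.name or mid)
        sp.setCompartment(_sanitize_id(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    # shared flux-bound parameters, one per distinct value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = smodel.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids = set()
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        sr = smodel.createReaction()
        sr.setId(_sanitize_id(rid))
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sanitize_id(met))
            ref.setConstant(True)
        _set_notes(
            sr,
            {
                "SUBSYSTEM": rxn.subsystem,
                "CATEGORY": rxn.category,
                "EVIDENCE": rxn.evidence,
                "GENE_ASSOCIATION": rxn.gene_association,
            },
        )
        for g in sorted(
            set(re.split(r"[()\s]+", rxn.gene_association)) - {"", "and", "or"}
        ):
            gene_ids.add(g)

    for g in sorted(gene_ids | model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sanitize_id("G_" + g))
        gp.setLabel(g)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType(
            "maximize" if model.objective_direction == "max" else "minimize"
        )
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize_id(model.objective))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str) -> MetabolicModel:
    """Load a model from SBML (L3+FBC, or L2 with kinetic-law bounds)."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(
            f"SBML parse error in {path} at line {err.getLine()}: {err.getMessage()}"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise ValueError(f"{path}: no model element found")

    model = MetabolicModel(
        _unsanitize_id(smodel.getId() or "model"), smodel.getName() or ""
    )
    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        model.compartments[_unsanitize_id(comp.getId())] = (
            comp.getName() or _unsanitize_id(comp.getId())
        )

    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        elif sp.isSetCharge():  # legacy L2
            charge = sp.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_unsanitize_id(sp.getId()),
                name=sp.getName() or "",
                compartment=_unsanitize_id(sp.getCompartment()),
                formula=formula,
                charge=charge,
            )
        )

    defaulted = []
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        rid = _unsanitize_id(sr.getId())
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _unsanitize_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _unsanitize_id(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()

        lb = ub = None
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = smodel.getParameter(rplug.getLowerFluxBound()).getValue()
        if rplug is not None and rplug.isSetUpperFluxBound():
            ub = smodel.getParameter(rplug.getUpperFluxBound()).getValue()
        if lb is None and sr.isSetKineticLaw():  # legacy bound annotations
            kl = sr.getKineticLaw()
            for k in range(kl.getNumParameters()):
                par = kl.getParameter(k)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
        if lb is None or ub is None:
            rev = sr.getReversible()
            lb = DEFAULT_LB if (lb is None and rev) else (lb or 0.0)
            ub = DEFAULT_UB if ub is None else ub
            defaulted.append(rid)

        notes = _notes_dict(sr)
        category = notes.get("CATEGORY", "")
        if category not in REACTION_CATEGORIES:
            category = "exchange" if len(stoich) == 1 else "metabolic"
        evidence = notes.get("EVIDENCE", "annotated")
        if evidence not in EVIDENCE_TAGS:
            evidence = "annotated"
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=sr.getName() or "",
                subsystem=notes.get("SUBSYSTEM", ""),
                category=category,
                gene_association=notes.get("GENE_ASSOCIATION", ""),
                evidence=evidence,
            )
        )
    if defaulted:
        log.warning(
            "no flux bounds for %d reactions; defaulted to %g/%g (irreversible 0/%g): %s",
            len(defaulted),
            DEFAULT_LB,
            DEFAULT_UB,
            DEFAULT_UB,
            ", ".join(defaulted[:10]),
        )

    mplug = smodel.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            model.genes.add(gp.getLabel() or _unsanitize_id(gp.getId()))
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = _unsanitize_id(obj.getFluxObjective(0).getReaction())
            model.objective_direction = (
                "max" if obj.getType() == "maximize" else "min"
            )
    return model
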