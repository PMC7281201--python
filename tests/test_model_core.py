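"""Stoichiometric container, matrix construction, balance and SBML I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyanogem.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_matrix,
    check_mass_balance,
    count_by_category,
    format_formula,
    models_equal,
    parse_formula,
)
from cyanogem.sbml_io import read_sbml, write_sbml


def small_model():
    m = MetabolicModel("small")
    for mid, formula in [("a_e", "C6H12O6"), ("a_c", "C6H12O6"), ("b_c", "C3H6O3")]:
        m.add_metabolite(
            Metabolite(mid, compartment="extracellular" if mid.endswith("_e") else "cytosol",
                       formula=parse_formula(formula))
        )
    m.add_reaction(Reaction("EX_a", {"a_e": -1.0}, -10, 1000, category="exchange"))
    m.add_reaction(Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0, 1000,
                            category="transport", gene_association="g1 or g2"))
    # deliberately drops half the carbon: exercises the balance checker
    m.add_reaction(Reaction("SPLIT", {"a_c": -1.0, "b_c": 1.0}, 0, 1000,
                            subsystem="Glycolysis"))
    return m


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "text,expect",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CH1.59O0.57", {"C": 1, "H": 1.59, "O": 0.57}),
            ("C55H72MgN4O5", {"C": 55, "H": 72, "Mg": 1, "N": 4, "O": 5}),
            ("", {}),
        ],
    )
    def test_parse(self, text, expect):
        assert parse_formula(text) == pytest.approx(expect)

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_formula("C6(H2O)6")

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S", "Mg"]),
            st.integers(min_value=1, max_value=60),
            min_size=1,
            max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, counts):
        assert parse_formula(format_formula(counts)) == pytest.approx(counts)


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A", compartment="cytosol"))
        m.add_metabolite(Metabolite("B", compartment="cytosol"))
        m.add_reaction(Reaction("R", {"A": -1.0, "B": 1.0}))
        N, mets, rxns = build_matrix(m)
        col = dict(zip(mets, N.toarray()[:, rxns.index("R")]))
        assert col == {"A": -1.0, "B": 1.0}

    def test_empty_model(self):
        N, mets, rxns = build_matrix(MetabolicModel())
        assert N.shape == (0, 0) and mets == [] and rxns == []

    def test_matrix_product_matches_direct_summation(self, toy_model):
        """N·v equals per-metabolite accumulation computed reaction by reaction."""
        N, mets, rxns = build_matrix(toy_model)
        rng = np.random.default_rng(42)
        v = rng.normal(size=len(rxns))
        direct = {mid: 0.0 for mid in mets}
        for rid, flux in zip(rxns, v):
            for mid, coef in toy_model.reactions[rid].stoichiometry.items():
                direct[mid] += coef * flux
        np.testing.assert_allclose(
            N @ v, [direct[mid] for mid in mets], atol=1e-12
        )


class TestMassBalance:
    def _two_met_model(self, fa, fb, coeff_b=1.0):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A", compartment="cytosol", formula=parse_formula(fa)))
        m.add_metabolite(Metabolite("B", compartment="cytosol", formula=parse_formula(fb)))
        m.add_reaction(Reaction("R", {"A": -1.0, "B": coeff_b}))
        return m

    def test_balanced_isomerization(self):
        imb, skipped = check_mass_balance(self._two_met_model("CH2O", "CH2O"))
        assert imb == {} and skipped == []

    def test_balanced_cleavage(self):
        imb, _ = check_mass_balance(self._two_met_model("C6H12O6", "C3H6O3", 2.0))
        assert imb == {}

    def test_imbalanced_flagged_with_net_atoms(self):
        imb, _ = check_mass_balance(self._two_met_model("C6H12O6", "C3H6O3", 1.0))
        assert imb["R"] == pytest.approx({"C": -3, "H": -6, "O": -3})

    def test_missing_formula_skipped(self):
        m = self._two_met_model("CH2O", "CH2O")
        m.metabolites["B"].formula = None
        imb, skipped = check_mass_balance(m)
        assert skipped == ["R"] and imb == {}

    def test_boundary_categories_exempt(self):
        m = small_model()
        imb, _ = check_mass_balance(m)
        # EX_a is category exchange; SPLIT is genuinely imbalanced
        assert "EX_a" not in imb and "SPLIT" in imb


class TestCategoryCounts:
    def test_counts_partition_reactions(self, toy_model):
        by_cat, by_sub = count_by_category(toy_model)
        assert sum(by_cat.values()) == len(toy_model.reactions)
        assert sum(by_sub.values()) == len(toy_model.reactions)

    def test_generator_declared_counts(self, toy_model):
        by_cat, _ = count_by_category(toy_model)
        assert by_cat["exchange"] == 8
        assert by_cat["biomass"] == 1
        assert by_cat["maintenance"] == 1
        assert by_cat["sink"] == 1

    def test_empty_model(self):
        by_cat, by_sub = count_by_category(MetabolicModel())
        assert by_cat == {} and by_sub == {}


class TestSbmlRoundTrip:
    def test_small_model_round_trip_identity(self, tmp_path):
        m = small_model()
        path = tmp_path / "small.xml"
        write_sbml(m, path)
        assert models_equal(m, read_sbml(path))

    def test_toy_round_trip_identity(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        again = read_sbml(path)
        assert models_equal(toy_model, again)
        assert again.objective == toy_model.objective
        assert again.genes == toy_model.genes

    def test_double_round_trip_stable(self, toy_model, tmp_path):
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml(toy_model, p1)
        write_sbml(read_sbml(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_independent_library_can_read_export(self, toy_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(toy_model.reactions)
        assert len(cm.metabolites) == len(toy_model.metabolites)
        ex = cm.reactions.get_by_id("EX_photon")
        assert (ex.lower_bound, ex.upper_bound) == toy_model.reactions["EX_photon"].bounds

    def test_malformed_xml_reports_parse_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model></sbml>")
        with pytest.raises(ValueError, match="line"):
            read_sbml(bad)

    def test_missing_bounds_defaulted_with_warning(self, tmp_path, caplog):
        # minimal legacy L2 file without bound annotations
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="B" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="R1" reversible="true">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
   <reaction id="R2" reversible="false">
    <listOfReactants><speciesReference species="B"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""
        path = tmp_path / "legacy.xml"
        path.write_text(text)
        import logging

        with caplog.at_level(logging.WARNING, logger="cyanogem.sbml_io"):
            m = read_sbml(path)
        assert m.reactions["R1"].bounds == (-1000.0, 1000.0)
        assert m.reactions["R2"].bounds == (0.0, 1000.0)
        assert any("defaulted" in r.message for r in caplog.records)

    def test_id_sanitization_reversible(self, tmp_path):
        m = MetabolicModel("weird")
        m.add_metabolite(Metabolite("glc-D[e]", compartment="extracellular"))
        m.add_reaction(Reaction("EX_glc-D(e)", {"glc-D[e]": -1.0}, category="exchange"))
        path = tmp_path / "weird.xml"
        write_sbml(m, path)
        again = read_sbml(path)
        assert "EX_glc-D(e)" in again.reactions
        assert "glc-D[e]" in again.metabolites


class TestModelInvariants:
    def test_reaction_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Reaction("R", {"A": -1.0}, lower_bound=5, upper_bound=1)

    def test_reaction_rejects_empty_stoichiometry(self):
        with pytest.raises(ValueError):
            Reaction("R", {})

    def test_unknown_metabolite_rejected(self):
        m = MetabolicModel()
        with pytest.raises(ValueError, match="unknown metabolites"):
            m.add_reaction(Reaction("R", {"ghost": -1.0}))

    def test_duplicate_ids_rejected(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A", compartment="cytosol"))
        with pytest.raises(ValueError):
            m.add_metabolite(Metabolite("A", compartment="cytosol"))

    def test_exchange_detection_heuristic(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A", compartment="extracellular"))
        m.add_metabolite(Metabolite("B", compartment="cytosol"))
        # untagged: single-metabolite heuristic applies
        m.add_reaction(Reaction("X", {"A": -1.0}))
        m.add_reaction(Reaction("T", {"A": -1.0, "B": 1.0}))
        assert [r.id for r in m.exchanges()] == ["X"]
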