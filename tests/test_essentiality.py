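"""Reaction-deletion screening, active-reaction counts, energy scans."""

import pytest

from cyanogem.essentiality import (
    AnalysisSettings,
    active_in_any_optimum,
    active_reactions,
    energy_sensitivity_scan,
    essential_reactions,
    subsystem_summary,
)
from cyanogem.fba import FluxState, solve_pfba
from cyanogem.model import MetabolicModel, Metabolite, Reaction
from cyanogem.toy import toy_composition


def parallel_paths_model():
    """Two interchangeable routes from substrate to product."""
    m = MetabolicModel("parallel")
    for mid in ("s_c", "m1_c", "m2_c", "p_c"):
        m.add_metabolite(Metabolite(mid, compartment="cytosol"))
    m.add_reaction(Reaction("SRC", {"s_c": 1.0}, 0, 10))
    m.add_reaction(Reaction("PATH_A1", {"s_c": -1.0, "m1_c": 1.0}, 0, 1000))
    m.add_reaction(Reaction("PATH_A2", {"m1_c": -1.0, "p_c": 1.0}, 0, 1000))
    m.add_reaction(Reaction("PATH_B1", {"s_c": -1.0, "m2_c": 1.0}, 0, 1000))
    m.add_reaction(Reaction("PATH_B2", {"m2_c": -1.0, "p_c": 1.0}, 0, 1000))
    m.add_reaction(Reaction("OBJ", {"p_c": -1.0}, 0, 1000, category="demand"))
    m.objective = "OBJ"
    return m


class TestEssentialScreen:
    def test_biomass_deletion_is_essential(self, toy_model, photo_constraints):
        report = essential_reactions(toy_model, photo_constraints)
        assert "BIOMASS" in report.essential

    def test_parallel_pathways_are_individually_dispensable(self):
        m = parallel_paths_model()
        report = essential_reactions(m, objective="OBJ")
        for rid in ("PATH_A1", "PATH_A2", "PATH_B1", "PATH_B2"):
            assert rid not in report.essential
        assert {"SRC", "OBJ"} <= report.essential

    def test_full_screen_matches_generator_ground_truth(
        self, toy_model, toy_truth, photo_constraints
    ):
        report = essential_reactions(toy_model, photo_constraints)
        assert report.essential == toy_truth.essential

    def test_screen_matches_independent_backend_brute_force(
        self, toy_model, photo_constraints, tmp_path
    ):
        """Per-reaction knockout via cobrapy/GLPK yields the same essential set."""
        cobra = pytest.importorskip("cobra")
        from cyanogem.sbml_io import write_sbml

        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        cm.solver = "glpk"
        cm.objective = "BIOMASS"
        cm.reactions.get_by_id("ATPM").bounds = (1.3, 1.3)
        threshold = AnalysisSettings().essentiality_growth_threshold
        cobra_essential = set()
        for rxn in cm.reactions:
            with cm:
                rxn.bounds = (0.0, 0.0)
                growth = cm.slim_optimize(error_value=0.0)
            if growth <= threshold:
                cobra_essential.add(rxn.id)
        ours = essential_reactions(toy_model, photo_constraints)
        assert ours.essential == cobra_essential

    def test_counts_are_consistent(self, toy_model, photo_constraints):
        report = essential_reactions(toy_model, photo_constraints)
        assert report.n_screened == len(toy_model.reactions)
        non_essential = report.n_screened - report.n_essential
        assert non_essential == sum(
            1 for g in report.growth_after_deletion.values()
            if g > AnalysisSettings().essentiality_growth_threshold
        )
        frame = report.to_frame(toy_model)
        assert frame["essential"].sum() == report.n_essential

    def test_zero_flux_deletion_keeps_max_growth(
        self, toy_model, toy_truth, photo_constraints
    ):
        """Deleting a reaction idle in the unique optimum cannot change growth."""
        report = essential_reactions(toy_model, photo_constraints)
        for rid in ("OGDC", "SSADH", "T_ac", "EX_ac"):
            assert abs(toy_truth.pfba_fluxes[rid]) < 1e-9
            assert report.growth_after_deletion[rid] == pytest.approx(
                report.baseline_growth, rel=1e-6
            )

    def test_growth_fixation_released_for_screen(
        self, toy_model, toy_truth, photo_constraints
    ):
        photo_constraints.fixed_growth = toy_truth.max_growth
        report = essential_reactions(toy_model, photo_constraints)
        # with the fixation kept every deletion would be infeasible
        assert report.essential == toy_truth.essential

    def test_order_invariance(self, toy_model, photo_constraints):
        subset = ["CBB", "EX_ac", "PSET", "OGDC"]
        fwd = essential_reactions(toy_model, photo_constraints, reactions=subset)
        rev = essential_reactions(toy_model, photo_constraints, reactions=subset[::-1])
        assert fwd.growth_after_deletion == rev.growth_after_deletion

    def test_infeasible_baseline_aborts(self, toy_model, photo_constraints):
        photo_constraints.medium["EX_photon"] = (0.0, 0.0)
        photo_constraints.o2_evolution = (1.0, 0.0)  # demands O2 with no light
        with pytest.raises(RuntimeError, match="baseline"):
            essential_reactions(toy_model, photo_constraints)


class TestActiveReactions:
    def test_zero_flux_state_has_no_active_reactions(self, toy_model):
        state = FluxState({rid: 0.0 for rid in toy_model.reaction_ids}, 0.0, "optimal")
        active, _ = active_reactions(state)
        assert active == set()

    def test_threshold_classification(self):
        state = FluxState({"a": 1e-9, "b": 1e-7, "c": -0.5}, 0.0, "optimal")
        active, _ = active_reactions(state)
        assert active == {"b", "c"}
        loose, _ = active_reactions(
            state, AnalysisSettings(active_flux_threshold=1e-12)
        )
        assert loose == {"a", "b", "c"}

    def test_toy_pfba_active_set_equals_route_support(
        self, toy_model, toy_truth, photo_constraints
    ):
        photo_constraints.fixed_growth = toy_truth.max_growth
        state = solve_pfba(toy_model, photo_constraints)
        active, by_sub = active_reactions(state, model=toy_model)
        support = {
            rid for rid, v in toy_truth.pfba_fluxes.items() if abs(v) > 1e-9
        }
        assert active == support
        assert sum(by_sub.values()) == len(active)

    def test_degeneracy_superset_via_variability(
        self, toy_model, toy_truth, photo_constraints
    ):
        photo_constraints.fixed_growth = toy_truth.max_growth * 0.8
        state = solve_pfba(toy_model, photo_constraints)
        point_active, _ = active_reactions(state)
        any_active = active_in_any_optimum(toy_model, photo_constraints)
        assert point_active <= any_active

    def test_non_optimal_state_rejected(self):
        with pytest.raises(ValueError):
            active_reactions(FluxState({}, float("nan"), "infeasible"))

    def test_subsystem_summary_is_consistent(
        self, toy_model, toy_truth, photo_constraints
    ):
        """Per subsystem: essential <= total and active <= total."""
        photo_constraints.fixed_growth = toy_truth.max_growth
        state = solve_pfba(toy_model, photo_constraints)
        active, _ = active_reactions(state, model=toy_model)
        report = essential_reactions(toy_model, photo_constraints)
        frame = subsystem_summary(toy_model, active, report.essential)
        assert (frame["essential"] <= frame["total"]).all()
        assert (frame["active"] <= frame["total"]).all()
        assert frame["total"].sum() == len(toy_model.reactions)


class TestEnergySensitivity:
    def test_scan_over_parameter_grid(self, toy_model, toy_spec, photo_constraints):
        photo_constraints.fixed_growth = 0.05
        frame = energy_sensitivity_scan(
            toy_model,
            toy_spec.composition,
            {"glutamyl": "glu_c", "glucosyl": "glucan_c", "palmitoyl": "palm_c"},
            gam_values=[35.0, 40.0, 53.0],
            ngam_values=[1.3, 3.0, 4.0, 5.0],
            constraints=photo_constraints,
        )
        assert len(frame) == 12
        assert (frame["status"] == "optimal").all()
        # photon demand strictly increases with NGAM at fixed GAM
        for gam, sub in frame.groupby("gam"):
            photon = sub.sort_values("ngam")["photon_uptake"].to_numpy()
            assert (photon[1:] > photon[:-1]).all()
        # and increases with GAM at fixed NGAM (more ATP per unit biomass)
        for ngam, sub in frame.groupby("ngam"):
            photon = sub.sort_values("gam")["photon_uptake"].to_numpy()
            assert (photon[1:] > photon[:-1]).all()

    def test_base_parameters_reproduce_base_solution(
        self, toy_model, toy_spec, photo_constraints
    ):
        photo_constraints.fixed_growth = 0.05
        frame = energy_sensitivity_scan(
            toy_model,
            toy_spec.composition,
            {"glutamyl": "glu_c", "glucosyl": "glucan_c", "palmitoyl": "palm_c"},
            gam_values=[toy_spec.energy.gam],
            ngam_values=[toy_spec.energy.ngam],
            constraints=photo_constraints,
        )
        assert frame.loc[0, "central_l1"] == pytest.approx(0.0, abs=1e-6)

    def test_relaxing_ngam_never_increases_total_flux(
        self, toy_model, toy_spec, photo_constraints
    ):
        photo_constraints.fixed_growth = 0.05
        frame = energy_sensitivity_scan(
            toy_model,
            toy_spec.composition,
            {"glutamyl": "glu_c", "glucosyl": "glucan_c", "palmitoyl": "palm_c"},
            gam_values=[toy_spec.energy.gam],
            ngam_values=[0.0, toy_spec.energy.ngam],
            constraints=photo_constraints,
        )
        totals = frame.sort_values("ngam")["total_flux"].to_numpy()
        assert totals[0] <= totals[1] + 1e-9

    def test_infeasible_cells_marked_and_scan_continues(
        self, toy_model, toy_spec, photo_constraints
    ):
        photo_constraints.fixed_growth = 0.13
        frame = energy_sensitivity_scan(
            toy_model,
            toy_spec.composition,
            {"glutamyl": "glu_c", "glucosyl": "glucan_c", "palmitoyl": "palm_c"},
            gam_values=[toy_spec.energy.gam],
            ngam_values=[1.3, 500.0],  # second cell exceeds the photon budget
            constraints=photo_constraints,
        )
        assert frame.loc[0, "status"] == "optimal"
        assert frame.loc[1, "status"] == "infeasible"
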