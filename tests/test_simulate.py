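"""FBA/pFBA/LMOMA/MiMBL behaviour on the hand-checkable core network.

The frozen expected values below were computed two independent ways: by
hand on the lumped stoichiometry (glucose −10 → 20 pyruvate, 20 ATP,
20 NADH; biomass needs 2 pyruvate + 12 ATP, so optimal growth is exactly
8) and with the dense interior-point oracle in ``btdflux.bruteforce``.
"""

import numpy as np
import pytest

from btdflux import (
    Condition,
    MetabolicModel,
    Metabolite,
    Modification,
    Reaction,
    apply_modification,
    fba,
    feasibility_audit,
    lmoma,
    mimbl,
    pfba,
    reference_state,
    turnovers,
)
from btdflux.fixtures import FixtureSpec, random_consistent_model, random_fixture_condition
from btdflux.model import apply_condition
from btdflux.simulate import SolverError


class TestFBA:
    def test_no_carbon_no_growth(self, btd_core):
        cond = Condition("starve", {"EX_glc": (0.0, 1000.0)}, "EX_glc", 6,
                         ("EX_glc", "EX_glyc"))
        sol = fba(btd_core, condition=cond)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_glucose_growth_matches_hand_value(self, glucose_model):
        sol = fba(glucose_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(8.0, abs=1e-9)

    def test_solution_satisfies_constraints(self, glucose_model):
        audit = feasibility_audit(glucose_model, fba(glucose_model))
        assert audit["steady_state"] <= 1e-6
        assert audit["bounds"] <= 1e-6

    def test_infeasible_reported_not_raised(self, btd_core):
        broken = btd_core.copy()
        # force respiration while closing oxygen: no steady state exists
        broken.get_reaction("RESP").lower_bound = 5.0
        broken.get_reaction("EX_o2").lower_bound = 0.0
        sol = fba(broken)
        assert sol.status == "infeasible"


class TestPFBA:
    def test_growth_equals_fba_growth(self, glucose_model):
        assert pfba(glucose_model).objective_value == pytest.approx(
            fba(glucose_model).objective_value, abs=1e-9
        )

    def test_unique_pathway_equals_fba(self):
        """On a linear chain there are no alternate optima to trim."""
        model = random_consistent_model(FixtureSpec(seed=5, n_extra_reactions=0))
        conditioned = apply_condition(model, random_fixture_condition(model))
        f, p = fba(conditioned), pfba(conditioned)
        for rid in conditioned.reaction_ids():
            assert p.fluxes[rid] == pytest.approx(f.fluxes[rid], abs=1e-7)

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_total_flux_not_above_fba(self, seed):
        model = random_consistent_model(FixtureSpec(seed=seed))
        conditioned = apply_condition(model, random_fixture_condition(model))
        f, p = fba(conditioned), pfba(conditioned)
        fba_total = sum(abs(v) for v in f.fluxes.values())
        assert p.total_flux <= fba_total + 1e-6


class TestReferenceState:
    def test_turnover_hand_example(self):
        """A metabolite made and used by two unit reactions at flux 5 has τ=5."""
        mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c"),
                Metabolite("b_e", compartment="e")]
        rxns = [
            Reaction("EX_a", {"a_e": -1}, -5.0, -5.0, is_exchange=True),
            Reaction("T", {"a_e": -1, "a_c": 1}, 0, 1000),
            Reaction("S", {"a_c": -1, "b_e": 1}, 0, 1000),
            Reaction("EX_b", {"b_e": -1}, 0, 1000, is_exchange=True),
        ]
        model = MetabolicModel("tiny", mets, rxns, [], objective_reaction="EX_b")
        sol = fba(model)
        tau = turnovers(model, sol.fluxes)
        assert tau["a_c"] == pytest.approx(5.0)

    def test_dead_end_turnover_zero(self, glucose_model, glucose_reference):
        assert glucose_reference.turnovers["ddm_c"] == 0.0

    def test_reference_tracks_condition(self, btd_core, presets):
        ref_glc = reference_state(btd_core, presets["glucose"])
        ref_gly = reference_state(btd_core, presets["glycerol"])
        assert ref_glc.flux("GLYCOLYSIS") > 0 and ref_glc.flux("GLYCENT") == 0
        assert ref_gly.flux("GLYCENT") > 0 and ref_gly.flux("GLYCOLYSIS") == 0

    def test_zero_growth_has_no_reference(self, btd_core):
        cond = Condition("starve", {"EX_glc": (0.0, 1000.0)}, "EX_glc", 6,
                         ("EX_glc", "EX_glyc"))
        with pytest.raises(SolverError, match="not positive"):
            reference_state(btd_core, cond)


class TestLMOMA:
    def test_identity(self, glucose_model, glucose_reference):
        sol = lmoma(glucose_model, glucose_reference)
        assert sol.objective_value == 0.0
        for rid, w in glucose_reference.fluxes.items():
            assert sol.fluxes[rid] == pytest.approx(w, abs=1e-6)

    def test_zero_flux_knockout_costs_nothing(self, glucose_model, glucose_reference):
        # BTDt carries no wildtype flux aerobically; deleting it is free
        assert glucose_reference.flux("BTDt") == 0.0
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "BTDt", 0.0))
        assert lmoma(mutant, glucose_reference).objective_value == 0.0

    def test_infeasible_perturbation_status(self, glucose_model, glucose_reference):
        mutant = glucose_model.copy()
        mutant.get_reaction("RESP").lower_bound = 5.0
        mutant.get_reaction("EX_o2").lower_bound = 0.0
        mutant.get_reaction("EX_o2").upper_bound = 0.0
        assert lmoma(mutant, glucose_reference).status == "infeasible"

    def test_growth_is_an_outcome(self, glucose_model, glucose_reference):
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "O2t", 1 / 16))
        sol = lmoma(mutant, glucose_reference)
        assert sol.optimal
        assert 0 < sol.growth < glucose_reference.growth


class TestMiMBL:
    def test_identity(self, glucose_model, glucose_reference):
        assert mimbl(glucose_model, glucose_reference).objective_value == 0.0

    def test_perturbed_satisfies_constraints(self, glucose_model, glucose_reference):
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "O2t", 1 / 16))
        sol = mimbl(mutant, glucose_reference)
        assert sol.optimal and sol.objective_value > 0
        audit = feasibility_audit(mutant, sol)
        assert audit["steady_state"] <= 1e-6 and audit["bounds"] <= 1e-6
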