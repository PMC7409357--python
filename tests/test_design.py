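"""Modification semantics, BPCY, enumeration and the SPEA2 optimizer."""

import pytest

from btdflux import (
    DesignCandidate,
    Modification,
    OptimizerConfig,
    apply_candidate,
    apply_modification,
    bpcy,
    enumerate_designs,
    evaluate_candidate,
    fba,
    spea2_optimize,
)
from btdflux.model import apply_condition
from btdflux.simulate import reference_state


@pytest.fixture(scope="module")
def design_setup(drain_model, microaerobic):
    conditioned = apply_condition(drain_model, microaerobic)
    reference = reference_state(conditioned)
    return conditioned, reference


def small_config(**kw):
    defaults = dict(simulation_method="pfba", max_evaluations=600,
                    max_modifications=1, population_size=30, archive_size=30,
                    seed=0)
    defaults.update(kw)
    return OptimizerConfig(**defaults)


class TestApplyModification:
    def test_knockout_closes_reaction(self, glucose_model, glucose_reference):
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "BTDt", 0.0))
        rxn = mutant.get_reaction("BTDt")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        # no feasible flux can reach the product exchange any more
        assert fba(mutant, objective="EX_btd").objective_value == pytest.approx(0.0, abs=1e-9)

    def test_underexpression_caps_at_fraction_of_wildtype(self, glucose_model,
                                                          glucose_reference):
        w = glucose_reference.flux("O2t")
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "O2t", 1 / 16))
        rxn = mutant.get_reaction("O2t")
        assert rxn.lower_bound == 0.0
        assert rxn.upper_bound == pytest.approx(w / 16)

    def test_overexpression_floors_flux(self, glucose_model, glucose_reference):
        w = glucose_reference.flux("TCA")
        assert w > 0
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "TCA", 2.0))
        rxn = mutant.get_reaction("TCA")
        assert rxn.lower_bound == pytest.approx(2 * w)
        assert rxn.upper_bound == 1000.0
        assert mutant.infeasible_marker is None

    def test_overexpression_beyond_outer_bound_marks_infeasible(
            self, glucose_model, glucose_reference):
        # wildtype respiration is 36; a 32x floor exceeds the 1000 bound
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("reaction", "RESP", 32.0))
        assert mutant.infeasible_marker is not None

    def test_isozyme_knockout_leaves_model_unchanged(self, glucose_model,
                                                     glucose_reference):
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("gene", "alsB", 0.0))
        assert mutant == glucose_model  # ALS survives through alsA

    def test_gene_knockout_propagates_through_gpr(self, glucose_model,
                                                  glucose_reference):
        mutant = apply_modification(glucose_model, glucose_reference,
                                    Modification("gene", "alsA", 0.0))
        # ALS keeps its isozyme, the decarboxylase (alsA only) is lost
        assert mutant.get_reaction("ALS").upper_bound == 1000.0
        assert mutant.get_reaction("ALDC").upper_bound == 0.0

    def test_unknown_target_raises(self, glucose_model, glucose_reference):
        with pytest.raises(KeyError):
            apply_modification(glucose_model, glucose_reference,
                               Modification("reaction", "NOPE", 0.0))

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DesignCandidate((Modification("reaction", "O2t", 0.0),
                             Modification("reaction", "O2t", 2.0)))


class TestBPCY:
    def test_zero_growth_zero_score(self):
        assert bpcy(0.0, 6.06, -16.0) == 0.0

    def test_direct_arithmetic(self):
        assert bpcy(0.376, 6.06, -16.0) == pytest.approx(0.376 * 6.06 / 16)

    def test_linear_in_production(self):
        assert bpcy(0.4, 8.0, -16.0) == pytest.approx(2 * bpcy(0.4, 4.0, -16.0))

    def test_zero_uptake_guard(self):
        assert bpcy(0.5, 1.0, 0.0) == 0.0


class TestEnumerate:
    def test_counts(self, drain_model, microaerobic):
        cfg = small_config(targets=("O2t", "TCA", "DRAIN_ATP"))
        results = enumerate_designs(drain_model, microaerobic, "EX_btd",
                                    "EX_glc", cfg)
        assert len(results) == 1 + 3 * len(cfg.factor_grid)  # wildtype + grid

    def test_empty_targets_only_wildtype(self, drain_model, microaerobic):
        cfg = small_config(targets=())
        results = enumerate_designs(drain_model, microaerobic, "EX_btd",
                                    "EX_glc", cfg)
        assert len(results) == 1
        assert results[0].candidate.modifications == ()

    def test_budget_guard(self, drain_model, microaerobic):
        cfg = small_config(max_modifications=2, max_evaluations=600)
        with pytest.raises(ValueError, match="budget"):
            enumerate_designs(drain_model, microaerobic, "EX_btd", "EX_glc",
                              cfg, budget=10)

    def test_sorted_by_bpcy(self, drain_model, microaerobic):
        cfg = small_config(targets=("O2t", "DRAIN_ATP"))
        results = enumerate_designs(drain_model, microaerobic, "EX_btd",
                                    "EX_glc", cfg)
        scores = [r.bpcy for r in results]
        assert scores == sorted(scores, reverse=True)


class TestSPEA2:
    def test_zero_modifications_returns_wildtype(self, drain_model, microaerobic):
        cfg = small_config(max_modifications=0, population_size=5,
                           archive_size=5, max_evaluations=5)
        results = spea2_optimize(drain_model, microaerobic, "EX_btd", "EX_glc", cfg)
        assert len(results) == 1
        assert results[0].candidate.modifications == ()

    def test_seeded_determinism(self, drain_model, microaerobic):
        cfg = small_config(seed=42)
        runs = [spea2_optimize(drain_model, microaerobic, "EX_btd", "EX_glc", cfg)
                for _ in range(2)]
        keys = [[(r.candidate.key, r.bpcy, r.production) for r in run]
                for run in runs]
        assert keys[0] == keys[1]

    def test_archive_is_pareto_front(self, drain_model, microaerobic):
        results = spea2_optimize(drain_model, microaerobic, "EX_btd", "EX_glc",
                                 small_config(seed=3, max_modifications=2))
        objs = [(r.bpcy, r.production) for r in results]
        for a in objs:
            for b in objs:
                dominated = (a[0] >= b[0] and a[1] >= b[1]
                             and (a[0] > b[0] or a[1] > b[1]))
                assert not dominated or a == b

    def test_respects_evaluation_budget(self, drain_model, microaerobic):
        from btdflux.design import _Search, _default_targets
        conditioned = apply_condition(drain_model, microaerobic)
        reference = reference_state(conditioned)
        cfg = small_config(max_evaluations=120, population_size=40, seed=9)
        targets = _default_targets(conditioned, cfg, "EX_btd", "EX_glc")
        search = _Search(conditioned, reference, cfg, "EX_btd", "EX_glc", targets)
        search.run()
        assert search.evaluations <= 120

    def test_oracle_dominance(self, drain_model, microaerobic):
        """Exhaustive enumeration bounds every archive entry's BPCY."""
        cfg = small_config(targets=("O2t", "TCA", "DRAIN_ATP", "RESP"), seed=5)
        best = enumerate_designs(drain_model, microaerobic, "EX_btd", "EX_glc",
                                 cfg)[0]
        archive = spea2_optimize(drain_model, microaerobic, "EX_btd", "EX_glc", cfg)
        assert archive, "search returned an empty archive"
        for r in archive:
            assert r.bpcy <= best.bpcy + 1e-9

    def test_results_replay_outside_optimizer(self, design_setup, drain_model,
                                              microaerobic):
        conditioned, reference = design_setup
        archive = spea2_optimize(drain_model, microaerobic, "EX_btd", "EX_glc",
                                 small_config(seed=11))
        for r in archive[:5]:
            replay = evaluate_candidate(conditioned, reference, r.candidate,
                                        "pfba", "EX_btd", "EX_glc")
            assert replay.growth == pytest.approx(r.growth, abs=1e-8)
            assert replay.production == pytest.approx(r.production, abs=1e-8)

    def test_infeasible_wildtype_errors(self, btd_core):
        from btdflux import Condition
        from btdflux.simulate import SolverError
        starved = Condition("starve", {"EX_glc": (0.0, 1000.0)}, "EX_glc", 6,
                            ("EX_glc", "EX_glyc"))
        with pytest.raises(SolverError):
            spea2_optimize(btd_core, starved, "EX_btd", "EX_glc", small_config())


class TestEvaluateCandidate:
    def test_wildtype_matches_reference(self, design_setup):
        conditioned, reference = design_setup
        wt = evaluate_candidate(conditioned, reference, DesignCandidate(),
                                "pfba", "EX_btd", "EX_glc")
        assert wt.feasible
        assert wt.growth == pytest.approx(reference.growth, abs=1e-8)

    def test_infeasible_marker_scores_zero(self, design_setup):
        conditioned, reference = design_setup
        cand = DesignCandidate((Modification("reaction", "RESP", 32.0),))
        res = evaluate_candidate(conditioned, reference, cand, "pfba",
                                 "EX_btd", "EX_glc")
        assert not res.feasible and res.bpcy == 0.0

    @pytest.mark.parametrize("method", ["pfba", "lmoma", "mimbl"])
    def test_all_methods_score_candidates(self, design_setup, method):
        # halving oxygen transport keeps the drain-burdened mutant viable
        # while forcing NADH into the butanediol branch
        conditioned, reference = design_setup
        cand = DesignCandidate((Modification("reaction", "O2t", 0.5),))
        res = evaluate_candidate(conditioned, reference, cand, method,
                                 "EX_btd", "EX_glc")
        assert res.feasible
        assert res.production > 0
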