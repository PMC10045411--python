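"""GIMME extraction: consensus calls, GPR mapping, penalties, and the LP
against a brute-force arrangement-vertex oracle."""

import numpy as np
import pandas as pd
import pytest

from polytope_oracle import oracle_min_weighted_abs_flux
from rgem.gimme import (
    ExpressionCalls,
    OrthologTable,
    PenaltyVector,
    compute_penalties,
    consensus_presence,
    gpr_presence,
    map_orthologs,
    run_gimme,
)
from rgem.lp import InfeasibleModelError, solve_fba
from rgem.model import MetabolicModel, Metabolite, ModelValidationError, Reaction
from rgem.synth import random_network


def calls_frame(**genes):
    return pd.DataFrame({f"rep{i+1}": [v[i] for v in genes.values()]
                         for i in range(3)},
                        index=list(genes))


class TestConsensus:
    @pytest.mark.parametrize(
        "pattern,expected",
        [((True, True, False), True),    # P,P,A -> present (2-of-3)
         ((True, False, False), False),  # P,A,A -> absent
         ((False, False, False), False)],
    )
    def test_two_of_three_rule(self, pattern, expected):
        presence = consensus_presence(calls_frame(g=pattern))
        assert presence["g"] is expected

    def test_missing_replicate_counts_as_absent(self):
        frame = calls_frame(g=(True, True, False)).astype(object)
        frame.loc["g", "rep2"] = np.nan
        presence = consensus_presence(frame)
        assert presence["g"] is False

    def test_too_few_replicates_rejected(self):
        frame = pd.DataFrame({"rep1": [True]}, index=["g"])
        with pytest.raises(ValueError, match="min_present"):
            consensus_presence(frame)


class TestOrthologs:
    def test_direct_mapping(self):
        out = map_orthologs({"gA": True}, OrthologTable({"gA": "hA"}))
        assert out == {"hA": True}

    def test_many_to_one_any_present(self):
        table = OrthologTable({"g1": "hA", "g2": "hA"})
        out = map_orthologs({"g1": False, "g2": True}, table)
        assert out == {"hA": True}
        out = map_orthologs({"g1": False, "g2": False}, table)
        assert out == {"hA": False}

    def test_empty_table_warns_about_unmapped_model_genes(self):
        with pytest.warns(UserWarning, match="no ortholog mapping"):
            out = map_orthologs({"g1": True}, OrthologTable({}),
                                model_genes={"hA", "hB"})
        assert out == {}


class TestGprPresence:
    def test_or_and_and_no_gpr(self, parallel_model):
        state = gpr_presence(parallel_model, {"g1": False, "g2": True})
        assert state["R1"] == "absent"
        assert state["R2"] == "present"
        assert state["EX_A"] == "no_gpr"

    def test_malformed_gpr_raises(self):
        mets = [Metabolite("A_c", compartment="c")]
        model = MetabolicModel(
            mets, [Reaction("R", {"A_c": -1.0}, 0, 1, gpr="g1 and")]
        )
        with pytest.raises(ModelValidationError, match="malformed"):
            gpr_presence(model, {})


class TestPenalties:
    def test_binary_encoding(self):
        pv = compute_penalties({"R1": "absent", "R2": "present", "R3": "no_gpr"})
        assert pv.c == {"R1": 0.5, "R2": 0.0, "R3": 0.0}
        assert pv.x == {"R1": 0.0, "R2": 1.0, "R3": 1.0}

    def test_all_present_gives_zero_vector(self):
        pv = compute_penalties({"R1": "present", "R2": "present"})
        assert set(pv.c.values()) == {0.0}

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltyVector(c={"R1": -1.0}, x={"R1": 2.0})


class TestRunGimme:
    def test_penalized_alternative_unused_when_free_path_exists(self, parallel_model):
        pv = compute_penalties(
            gpr_presence(parallel_model, {"g1": True, "g2": False}))
        result = run_gimme(parallel_model, pv, required_fraction=1.0)
        assert result.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert "R2" not in result.active_reactions
        assert "R1" in result.active_reactions

    def test_capped_penalized_paths_hand_solved_score(self, parallel_model):
        # both routes absent, each capped at 5: demand 10 forces 5+5,
        # score = 0.5*(5+5) = 5
        parallel_model.reaction("R1").upper_bound = 5.0
        parallel_model.reaction("R2").upper_bound = 5.0
        pv = compute_penalties(
            gpr_presence(parallel_model, {"g1": False, "g2": False}))
        result = run_gimme(parallel_model, pv, required_fraction=1.0)
        assert result.inconsistency_score == pytest.approx(5.0, abs=1e-6)
        assert {"R1", "R2"} <= result.active_reactions

    def test_all_present_keeps_every_reaction(self, toy_model):
        pv = compute_penalties({r.id: "present" for r in toy_model.reactions})
        result = run_gimme(toy_model, pv)
        assert result.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert result.active_reactions == set(toy_model.reaction_ids)

    def test_matches_arrangement_vertex_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 10:
            model = random_network(rng)
            opt = solve_fba(model).objective_value
            if opt <= 1e-6:
                continue
            rids = model.reaction_ids
            weights = {rid: 0.5 * float(rng.random() < 0.4) for rid in rids}
            pv = PenaltyVector(c=weights, x={r: 1 - 2 * w for r, w in weights.items()})
            result = run_gimme(model, pv, required_fraction=0.9)
            expected = oracle_min_weighted_abs_flux(model, weights, 0.9, opt)
            assert result.inconsistency_score == pytest.approx(expected, abs=1e-6)
            checked += 1

    def test_penalty_on_unused_reaction_leaves_score(self, parallel_model):
        pv = compute_penalties(
            gpr_presence(parallel_model, {"g1": True, "g2": False}))
        base = run_gimme(parallel_model, pv, 0.9).inconsistency_score
        pv.c["EX_A"] = 0.0  # EX_A is used; penalize R2 more instead
        pv.c["R2"] = 5.0
        again = run_gimme(parallel_model, pv, 0.9).inconsistency_score
        assert again == pytest.approx(base, abs=1e-9)

    def test_score_nondecreasing_in_required_fraction(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            model = random_network(rng)
            opt = solve_fba(model).objective_value
            if opt <= 1e-6:
                continue
            weights = {rid: 0.5 * float(rng.random() < 0.5)
                       for rid in model.reaction_ids}
            pv = PenaltyVector(c=weights, x={})
            scores = [run_gimme(model, pv, f).inconsistency_score
                      for f in (0.1, 0.5, 0.9, 1.0)]
            assert all(s2 >= s1 - 1e-9 for s1, s2 in zip(scores, scores[1:]))

    def test_active_submodel_retains_required_functionality(self, toy_model):
        from rgem.constraints import set_reference_exchanges
        from rgem.synth import METABOLITE_EXCHANGE_MAP, MODULE_GENES

        model, _ = set_reference_exchanges(toy_model, sorted(METABOLITE_EXCHANGE_MAP))
        presence = {g: g not in set(MODULE_GENES) for g in model.genes}
        pv = compute_penalties(gpr_presence(model, presence))
        result = run_gimme(model, pv, required_fraction=0.9)
        full_opt = solve_fba(model).objective_value
        sub = model.subset(result.active_reactions)
        sub_opt = solve_fba(sub).objective_value
        assert sub_opt >= 0.9 * full_opt - 1e-6

    def test_zero_score_iff_penalized_reactions_closable(self):
        """score == 0 exactly when the functionality constraint is attainable
        with zero flux through every penalized reaction (re-solve check)."""
        rng = np.random.default_rng(29)
        for _ in range(10):
            model = random_network(rng)
            opt = solve_fba(model).objective_value
            if opt <= 1e-6:
                continue
            weights = {rid: 0.5 * float(rng.random() < 0.5)
                       for rid in model.reaction_ids}
            pv = PenaltyVector(c=weights, x={})
            score = run_gimme(model, pv, 0.9).inconsistency_score
            closed = model.copy()
            for rid, w in weights.items():
                if w > 0:
                    rxn = closed.reaction(rid)
                    rxn.lower_bound = rxn.upper_bound = 0.0
            closed_sol = solve_fba(closed)
            attainable = (closed_sol.status == "optimal"
                          and closed_sol.objective_value >= 0.9 * opt - 1e-7)
            assert (score < 1e-6) == attainable

    def test_infeasible_functionality_constraint_raises(self, chain_model):
        chain_model.reaction("DM_B").lower_bound = 0.0
        chain_model.reaction("EX_A").lower_bound = 0.0  # optimum becomes 0
        pv = compute_penalties({r.id: "present" for r in chain_model.reactions})
        with pytest.warns(UserWarning, match="vacuous"):
            run_gimme(chain_model, pv, 0.9)
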