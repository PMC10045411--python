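"""Unit and property tests for the stoichiometric data model and I/O."""

import numpy as np
import pytest

from rgem.model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    binarize,
    build_stoichiometric_matrix,
    eval_gpr,
    gpr_genes,
    parse_formula,
    parse_gpr,
    read_model,
    validate_mass_charge_balance,
    write_model,
)
from rgem.synth import random_network


def small_model():
    mets = [Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")]
    rxns = [
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0, 10),
        Reaction("R2", {"B_c": -1.0}, 0, 10),
    ]
    return MetabolicModel(mets, rxns, objective_id="R2")


class TestStoichiometricMatrix:
    def test_definition_on_two_reaction_chain(self):
        S = build_stoichiometric_matrix(small_model())
        assert S.row_ids == ["A_c", "B_c"]
        assert S.col_ids == ["R1", "R2"]
        np.testing.assert_array_equal(S.values, [[-1, 0], [1, -1]])

    def test_empty_reaction_list_gives_zero_columns(self):
        model = MetabolicModel([Metabolite("A_c", compartment="c")], [])
        S = build_stoichiometric_matrix(model)
        assert S.values.shape == (1, 0)

    def test_columns_reconstruct_reactions_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            model = random_network(rng)
            S = build_stoichiometric_matrix(model)
            for j, rxn in enumerate(model.reactions):
                rebuilt = {
                    S.row_ids[i]: S.values[i, j]
                    for i in range(len(S.row_ids))
                    if S.values[i, j] != 0
                }
                assert rebuilt == rxn.stoichiometry

    def test_duplicate_ids_rejected(self):
        mets = [Metabolite("A_c"), Metabolite("A_c")]
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel(mets, [])


class TestBinarize:
    def test_sign_and_magnitude_erased(self):
        from rgem.model import StoichiometricMatrix

        S = StoichiometricMatrix(np.array([[-1.0, 0.0], [2.0, -1.0]]),
                                 ["A", "B"], ["R1", "R2"])
        np.testing.assert_array_equal(binarize(S).values, [[1, 0], [1, 1]])

    def test_all_zero_stays_zero(self):
        from rgem.model import StoichiometricMatrix

        S = StoichiometricMatrix(np.zeros((2, 3)), ["A", "B"], ["R1", "R2", "R3"])
        assert binarize(S).values.sum() == 0

    def test_sum_equals_nonzero_count_random(self):
        from rgem.model import StoichiometricMatrix

        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = rng.random((6, 9)) * (rng.random((6, 9)) < 0.3)
            S = StoichiometricMatrix(vals, [f"m{i}" for i in range(6)],
                                     [f"r{j}" for j in range(9)])
            assert binarize(S).values.sum() == np.count_nonzero(vals)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        model = random_network(rng)
        Sb = binarize(build_stoichiometric_matrix(model))
        np.testing.assert_array_equal(binarize(Sb).values, Sb.values)


class TestGPR:
    @pytest.mark.parametrize(
        "gpr,presence,expected",
        [
            ("g1 or g2", {"g1": False, "g2": True}, True),
            ("g1 and g2", {"g1": False, "g2": True}, False),
            ("g1 and (g2 or g3)", {"g1": True, "g2": False, "g3": True}, True),
            ("(g1 or g2) and (g3 or g4)", {"g1": True, "g3": False, "g4": False}, False),
        ],
    )
    def test_and_or_semantics(self, gpr, presence, expected):
        assert eval_gpr(gpr, presence) is expected

    def test_empty_gpr_is_none(self):
        assert eval_gpr("", {}) is None
        assert parse_gpr("   ") is None

    def test_genes_extracted(self):
        assert gpr_genes("g1 and (g2 or g1)") == {"g1", "g2"}

    @pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1 or g2", "g1 g2"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ModelValidationError, match="malformed"):
            parse_gpr(bad)


class TestMassChargeBalance:
    def test_superoxide_dismutase_fixture_balanced(self, toy_model):
        # 2 h_c + 2 o2s_c -> o2_c + h2o2_c: H 2=2, O 4=4, charge 0=0
        report = {r["reaction_id"]: r for r in validate_mass_charge_balance(toy_model)}
        assert report["SPODM"]["balanced"] is True
        assert report["SPODM"]["element_residuals"] == {}
        assert report["SPODM"]["charge_residual"] == 0

    def test_dehydroascorbate_reductase_fixture_balanced(self, toy_model):
        report = {r["reaction_id"]: r for r in validate_mass_charge_balance(toy_model)}
        assert report["DASCBR_1"]["balanced"] is True

    def test_doubling_reaction_flagged(self):
        # A -> 2A' (same species): mass created from nothing
        mets = [Metabolite("A_c", compartment="c", formula="C2H4", charge=0),
                Metabolite("B_c", compartment="c", formula="C2H4", charge=0)]
        model = MetabolicModel(
            mets, [Reaction("DOUBLE", {"A_c": -1.0, "B_c": 2.0}, 0, 1)]
        )
        rep = {r["reaction_id"]: r for r in validate_mass_charge_balance(model)}
        assert rep["DOUBLE"]["balanced"] is False
        assert rep["DOUBLE"]["element_residuals"] == {"C": 2.0, "H": 4.0}

    def test_formula_parser(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula("HO4P") == {"H": 1, "O": 4, "P": 1}
        assert parse_formula("Na") == {"Na": 1}
        with pytest.raises(ModelValidationError):
            parse_formula("6CH")

    def test_missing_formula_reported_unchecked(self):
        mets = [Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")]
        model = MetabolicModel(mets, [Reaction("R", {"A_c": -1.0, "B_c": 1.0}, 0, 1)])
        (entry,) = validate_mass_charge_balance(model)
        assert entry["checked"] is False


class TestIO:
    def test_json_round_trip_toy(self, toy_model, tmp_path):
        path = tmp_path / "toy.json"
        write_model(toy_model, str(path))
        back = read_model(str(path))
        assert back.metabolite_ids == toy_model.metabolite_ids
        assert back.reaction_ids == toy_model.reaction_ids
        assert back.objective_id == toy_model.objective_id
        for rxn in toy_model.reactions:
            other = back.reaction(rxn.id)
            assert other.stoichiometry == rxn.stoichiometry  # bit-exact
            assert (other.lower_bound, other.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
            assert other.gpr == rxn.gpr
            assert other.subsystem == rxn.subsystem
        for met in toy_model.metabolites:
            o = back.metabolite(met.id)
            assert (o.formula, o.charge, o.compartment) == (
                met.formula, met.charge, met.compartment)

    def test_sbml_round_trip_toy(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy_model, str(path))
        back = read_model(str(path))
        assert set(back.reaction_ids) == set(toy_model.reaction_ids)
        assert back.objective_id == toy_model.objective_id
        for rxn in toy_model.reactions:
            other = back.reaction(rxn.id)
            assert other.stoichiometry == rxn.stoichiometry
            assert (other.lower_bound, other.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
            assert other.subsystem == rxn.subsystem
            # GPR equality up to parse tree (parenthesization may differ)
            assert parse_gpr(other.gpr) == parse_gpr(rxn.gpr)

    def test_sbml_without_objective_rejected(self, tmp_path):
        mets = [Metabolite("A_c", compartment="c")]
        model = MetabolicModel(mets, [Reaction("EX_A", {"A_c": -1.0}, -1, 1)])
        path = tmp_path / "noobj.xml"
        write_model(model, str(path))
        with pytest.raises(ModelValidationError, match="objective"):
            read_model(str(path))

    def test_json_undeclared_metabolite_named_in_error(self, tmp_path):
        import json

        data = {
            "metabolites": [{"id": "a_c", "compartment": "c"}],
            "reactions": [{"id": "R1", "metabolites": {"x_c": -1.0},
                           "lower_bound": 0, "upper_bound": 1}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ModelValidationError, match="x_c"):
            read_model(str(path))

    def test_json_missing_bounds_rejected(self, tmp_path):
        import json

        data = {
            "metabolites": [{"id": "a_c", "compartment": "c"}],
            "reactions": [{"id": "R1", "metabolites": {"a_c": -1.0}}],
        }
        path = tmp_path / "nobounds.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ModelValidationError, match="bound"):
            read_model(str(path))

    def test_cobrapy_reads_our_json_and_agrees_on_fba(self, toy_model, tmp_path):
        """Independent cross-check: cobrapy consumes the JSON dialect and
        its FBA optimum matches ours."""
        cobra = pytest.importorskip("cobra")
        from rgem.lp import solve_fba

        path = tmp_path / "toy.json"
        write_model(toy_model, str(path))
        cm = cobra.io.load_json_model(str(path))
        sol = cm.optimize()
        ours = solve_fba(toy_model)
        assert sol.status == "optimal"
        assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6)
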