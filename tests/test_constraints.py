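"""Metabolomic fold changes, ANOVA, exchange classification and bound rules."""

import numpy as np
import pandas as pd
import pytest

from rgem.constraints import (
    ConstraintLedger,
    MetaboliteMeasurement,
    apply_fold_change_constraints,
    classify_exchanges,
    compute_fold_changes,
    set_reference_exchanges,
)
from rgem.lp import run_fva, solve_fba
from rgem.synth import METABOLITE_EXCHANGE_MAP


def make_design(n=6):
    samples = [f"WT_s{i}" for i in range(n)] + [f"KO_s{i}" for i in range(n)]
    return pd.DataFrame(
        {"condition": ["WT"] * n + ["KO"] * n,
         "batch": (["b1", "b2"] * n)[: 2 * n]},
        index=samples,
    )


class TestFoldChanges:
    def test_exact_doubling_gives_fold_two(self):
        design = make_design()
        wt = np.array([100.0, 110.0, 90.0, 105.0, 95.0, 100.0])
        table = pd.DataFrame([np.concatenate([wt, 2 * wt])],
                             index=["met1"], columns=design.index)
        (meas,) = compute_fold_changes(table, design)
        assert meas.fold_change == pytest.approx(2.0, abs=1e-12)
        assert meas.direction == "up"

    def test_identical_groups_fold_one_p_near_one(self):
        design = make_design()
        row = np.tile([100.0, 120.0, 80.0, 100.0, 120.0, 80.0], 2)
        table = pd.DataFrame([row], index=["met1"], columns=design.index)
        (meas,) = compute_fold_changes(table, design)
        assert meas.fold_change == pytest.approx(1.0, abs=1e-12)
        assert meas.p_value > 0.9

    def test_agrees_with_statsmodels_anova(self):
        """Dual route: our partial-F p-value vs statsmodels anova_lm."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(0)
        design = make_design()
        vals = np.exp(rng.normal(5, 0.3, size=(4, 12)))
        table = pd.DataFrame(vals, index=[f"m{i}" for i in range(4)],
                             columns=design.index)
        ours = compute_fold_changes(table, design)
        for i, meas in enumerate(ours):
            frame = design.copy()
            frame["y"] = np.log(vals[i])
            fit = ols("y ~ C(condition) + C(batch)", data=frame).fit()
            table_sm = anova_lm(fit, typ=2)
            expected = table_sm.loc["C(condition)", "PR(>F)"]
            assert meas.p_value == pytest.approx(expected, rel=1e-8)

    def test_planted_shift_power(self):
        """2-fold planted shift, sigma_log = 0.2, n = 6/6: condition factor
        significant at 0.05 in at least 95% of simulations."""
        rng = np.random.default_rng(123)
        design = make_design()
        cond = (design["condition"] == "KO").to_numpy(float)
        batch = (design["batch"] == "b2").to_numpy(float)
        hits = 0
        n_sim = 200
        rows = []
        for _ in range(n_sim):
            y = 5 + np.log(2) * cond + 0.1 * batch + rng.normal(0, 0.2, 12)
            rows.append(np.exp(y))
        table = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_sim)],
                             columns=design.index)
        meas = compute_fold_changes(table, design)
        hits = sum(m.p_value < 0.05 for m in meas)
        assert hits / n_sim >= 0.95

    def test_nonpositive_intensity_rejected(self):
        design = make_design()
        table = pd.DataFrame([np.zeros(12) + 1.0], index=["m"],
                             columns=design.index)
        table.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            compute_fold_changes(table, design)

    def test_missing_values_pairwise_complete_with_warning(self):
        design = make_design()
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(5, 0.2, size=(2, 12)))
        table = pd.DataFrame(vals, index=["m0", "m1"], columns=design.index)
        table.iloc[1, 3] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            meas = compute_fold_changes(table, design)
        assert all(np.isfinite(m.p_value) for m in meas)


class TestClassifyExchanges:
    def test_toy_exchange_classes(self, toy_model):
        classes = {c.exchange_reaction_id: c for c in classify_exchanges(toy_model)}
        # superoxide can only be shed; glucose only consumed; CO2 both ways;
        # sodium has no intracellular sink -> blocked
        assert classes["EX_o2s_e"].exchange_class == "secretion_only"
        assert classes["EX_glc__D_e"].exchange_class == "uptake_only"
        assert classes["EX_co2_e"].exchange_class == "bidirectional"
        assert classes["EX_na1_e"].exchange_class == "blocked"

    def test_ros_branch_removal_blocks_superoxide(self, toy_model_no_ros):
        classes = {c.exchange_reaction_id: c
                   for c in classify_exchanges(toy_model_no_ros)}
        assert classes["EX_o2s_e"].exchange_class == "blocked"


def toy_measurements():
    return [
        MetaboliteMeasurement("h2o2", 2.0, 1e-4),     # up, secretion-only -> R1
        MetaboliteMeasurement("glc__D", 0.5, 1e-4),   # down, uptake-only -> R4
        MetaboliteMeasurement("xan", 2.0, 1e-4),      # up, uptake-only -> R2
        MetaboliteMeasurement("co2", 2.0, 1e-4),      # bidirectional -> skipped
        MetaboliteMeasurement("ascb__L", 1.0, 1e-4),  # fold exactly 1 -> no-op
        MetaboliteMeasurement("lac__L", 2.0, 0.5),    # not significant
    ]


class TestBoundRules:
    @pytest.fixture()
    def prepared(self, toy_model):
        model, _ = set_reference_exchanges(toy_model, sorted(METABOLITE_EXCHANGE_MAP))
        classes = classify_exchanges(model)
        return model, classes

    def test_rule_values_and_exclusivity(self, prepared):
        model, classes = prepared
        by_id = {c.exchange_reaction_id: c for c in classes}
        constrained, ledger = apply_fold_change_constraints(
            model, toy_measurements(), classes, alpha=0.05,
            mapping=METABOLITE_EXCHANGE_MAP)
        rules = {e.reaction_id: e for e in ledger.entries}
        # R1: lb := 0.10 x max secretion, exact
        assert rules["EX_h2o2_e"].rule == "R1"
        assert rules["EX_h2o2_e"].new_lb == pytest.approx(
            0.10 * by_id["EX_h2o2_e"].fva_max, rel=1e-12)
        # R4: ub := 0.90 x max uptake (fva min), exact
        assert rules["EX_glc__D_e"].rule == "R4"
        assert rules["EX_glc__D_e"].new_ub == pytest.approx(
            0.90 * by_id["EX_glc__D_e"].fva_min, rel=1e-12)
        # R2: uptake capped at the 10% mark
        assert rules["EX_xan_e"].rule == "R2"
        assert rules["EX_xan_e"].new_lb == pytest.approx(
            0.10 * by_id["EX_xan_e"].fva_min, rel=1e-12)
        # one rule per exchange; bidirectional/insignificant/unit-fold untouched
        assert len([e for e in ledger.entries]) == 3
        skipped = {s["reaction_id"] for s in ledger.skipped}
        assert "EX_co2_e" in skipped
        assert solve_fba(constrained).status == "optimal"

    def test_new_bounds_lie_inside_prior_fva_range(self, prepared):
        model, classes = prepared
        by_id = {c.exchange_reaction_id: c for c in classes}
        _, ledger = apply_fold_change_constraints(
            model, toy_measurements(), classes, mapping=METABOLITE_EXCHANGE_MAP)
        for e in ledger.entries:
            cls = by_id[e.reaction_id]
            changed = e.new_lb if e.new_lb != e.old_lb else e.new_ub
            assert cls.fva_min - 1e-9 <= changed <= cls.fva_max + 1e-9
            assert e.new_lb <= e.new_ub

    def test_alpha_relaxation_only_adds_rows(self, prepared):
        model, classes = prepared
        meas = toy_measurements() + [MetaboliteMeasurement("alltn", 2.0, 0.07)]
        _, strict = apply_fold_change_constraints(
            model, meas, classes, alpha=0.05, mapping=METABOLITE_EXCHANGE_MAP)
        _, relaxed = apply_fold_change_constraints(
            model, meas, classes, alpha=0.10, mapping=METABOLITE_EXCHANGE_MAP)
        strict_set = {(e.reaction_id, e.rule, e.new_lb, e.new_ub)
                      for e in strict.entries}
        relaxed_set = {(e.reaction_id, e.rule, e.new_lb, e.new_ub)
                       for e in relaxed.entries}
        assert strict_set < relaxed_set

    def test_deterministic_ledger(self, prepared):
        model, classes = prepared
        frames = []
        for _ in range(2):
            _, ledger = apply_fold_change_constraints(
                model, toy_measurements(), classes, mapping=METABOLITE_EXCHANGE_MAP)
            frames.append(ledger.to_frame().to_csv(index=False))
        assert frames[0] == frames[1]


class TestReferenceExchanges:
    def test_substrate_reference_and_free_ions(self, toy_model):
        model, ledger = set_reference_exchanges(toy_model, ["glc__D"])
        glc = model.reaction("EX_glc__D_e")
        assert glc.lower_bound == -0.25
        assert glc.upper_bound == toy_model.reaction("EX_glc__D_e").upper_bound
        h2o = model.reaction("EX_h2o_e")
        assert (h2o.lower_bound, h2o.upper_bound) == (-1000.0, 1000.0)
        rules = {e.rule for e in ledger.entries}
        assert rules == {"free_ion", "reference_uptake"}

    def test_empty_mapped_list_touches_only_ions(self, toy_model):
        model, ledger = set_reference_exchanges(toy_model, [])
        assert {e.rule for e in ledger.entries} == {"free_ion"}
        assert len(ledger.entries) == 8

    def test_unknown_metabolite_warns_and_skips(self, toy_model):
        with pytest.warns(UserWarning, match="nosuchmet"):
            _, ledger = set_reference_exchanges(toy_model, ["nosuchmet"])
        assert ledger.skipped
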