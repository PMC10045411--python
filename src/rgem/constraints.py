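"""Translate plasma metabolomic fold changes into exchange-bound constraints.

Workflow: (1) a per-metabolite two-way ANOVA (condition + batch, additive,
on log intensities) yields a KO/WT fold change and p-value; (2) FVA
classifies each exchange as secretion-only, uptake-only, bidirectional or
blocked; (3) significant fold changes tighten exchange bounds by four
direction/class rules; (4) a reference uptake (0.25 mmol/gDW/h) is set for
measured substrates and an ion/water list exchanges freely.

Bound rules for a significant measurement (KO relative to WT):

=====  =========  ==============  ========================================
rule   direction  exchange class  new bound
=====  =========  ==============  ========================================
R1     up (>1)    secretion-only  lb := 0.10 × FVA max   (force secretion)
R2     up (>1)    uptake-only     lb := 0.10 × FVA min   (cap uptake)
R3     down (<1)  secretion-only  ub := 0.10 × FVA max   (cap secretion)
R4     down (<1)  uptake-only     ub := 0.90 × FVA min   (force uptake)
=====  =========  ==============  ========================================

R1 (10% of maximum secretion) and R4 (90% of maximum uptake) use the
stated fractions; R2/R3 are stated only as inequalities and default to the
symmetric 10% mark, exposed as configuration.  Bidirectional and blocked
exchanges are never constrained, only logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lp import InfeasibleModelError, run_fva, solve_fba
from .model import MetabolicModel

__all__ = [
    "MetaboliteMeasurement",
    "ExchangeClass",
    "ConstraintLedger",
    "LedgerEntry",
    "FREE_ION_METABOLITES",
    "compute_fold_changes",
    "classify_exchanges",
    "apply_fold_change_constraints",
    "set_reference_exchanges",
    "read_measurements_tsv",
    "read_mapping_tsv",
]

logger = logging.getLogger(__name__)

#: metabolites allowed unconstrained uptake/secretion (base names, no
#: compartment suffix): oxygen, sodium, potassium, iron, magnesium,
#: bicarbonate, protons, water
FREE_ION_METABOLITES = ("o2", "na1", "k", "fe2", "mg2", "hco3", "h", "h2o")

FVA_SIGN_TOL = 1e-9


@dataclass
class MetaboliteMeasurement:
    metabolite_id: str
    fold_change: float  # KO / WT ratio
    p_value: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fold_change) and self.fold_change > 0):
            raise ValueError(
                f"{self.metabolite_id}: fold_change must be finite and positive"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.metabolite_id}: invalid p_value {self.p_value}")

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1.0 else "down"


@dataclass
class ExchangeClass:
    exchange_reaction_id: str
    exchange_class: str  # secretion_only | uptake_only | bidirectional | blocked
    fva_min: float
    fva_max: float


@dataclass
class LedgerEntry:
    reaction_id: str
    old_lb: float
    old_ub: float
    new_lb: float
    new_ub: float
    rule: str  # R1 | R2 | R3 | R4 | reference_uptake | free_ion


@dataclass
class ConstraintLedger:
    """Audit trail: every modified bound, in application order."""

    entries: list[LedgerEntry] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def record(self, rxn, new_lb: float, new_ub: float, rule: str) -> None:
        self.entries.append(
            LedgerEntry(rxn.id, rxn.lower_bound, rxn.upper_bound, new_lb, new_ub, rule)
        )

    def skip(self, reaction_id: str, reason: str) -> None:
        self.skipped.append({"reaction_id": reaction_id, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"reaction_id": e.reaction_id, "old_lb": e.old_lb, "old_ub": e.old_ub,
                 "new_lb": e.new_lb, "new_ub": e.new_ub, "rule": e.rule}
                for e in self.entries
            ],
            columns=["reaction_id", "old_lb", "old_ub", "new_lb", "new_ub", "rule"],
        )

    def to_dict(self) -> dict:
        return {"entries": self.to_frame().to_dict(orient="records"),
                "skipped": list(self.skipped)}


# ---------------------------------------------------------------------------
# fold changes / two-way ANOVA
# ---------------------------------------------------------------------------


def _two_way_anova_condition_p(Y: np.ndarray, condition: np.ndarray,
                               batch: np.ndarray) -> np.ndarray:
    """Vectorized additive two-way ANOVA (condition + batch, no interaction).

    Returns the condition-factor p-value per column of Y via the partial
    F-test comparing the full model against the batch-only model (type-II
    sum of squares for this two-factor additive design).
    """
    n = Y.shape[0]
    cond_levels = pd.unique(condition)
    batch_levels = pd.unique(batch)
    cols = [np.ones(n)]
    for lvl in batch_levels[1:]:
        cols.append((batch == lvl).astype(float))
    X_red = np.column_stack(cols)
    for lvl in cond_levels[1:]:
        cols.append((condition == lvl).astype(float))
    X_full = np.column_stack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return np.sum(resid**2, axis=0)

    rss_full = rss(X_full)
    rss_red = rss(X_red)
    df_cond = len(cond_levels) - 1
    df_res = n - np.linalg.matrix_rank(X_full)
    if df_res <= 0:
        raise ValueError("two-way ANOVA: no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_cond) / (rss_full / df_res)
    F = np.where(rss_full <= 0, np.inf, F)
    p = stats.f.sf(F, df_cond, df_res)
    # identical groups: zero between-SS -> F ~ 0, p ~ 1
    return np.where(np.isnan(p), 1.0, p)


def compute_fold_changes(
    intensities: pd.DataFrame, design: pd.DataFrame
) -> list[MetaboliteMeasurement]:
    """Fold changes and condition p-values from raw intensity tables.

    Parameters
    ----------
    intensities
        metabolite × sample table of positive intensities.
    design
        sample × factor table with columns ``condition`` (labels containing
        "KO" and "WT") and ``batch``.

    The fold change is geometric-mean(KO) / geometric-mean(WT); the p-value
    comes from the additive two-way ANOVA on log intensities.  Missing
    values are dropped pairwise-complete (with a warning); non-positive
    intensities are an error.
    """
    if not {"condition", "batch"} <= set(design.columns):
        raise ValueError("design needs 'condition' and 'batch' columns")
    design = design.loc[intensities.columns]
    cond = design["condition"].to_numpy()
    batch = design["batch"].to_numpy()
    if not {"KO", "WT"} <= set(cond):
        raise ValueError("design conditions must include 'KO' and 'WT'")
    for label in ("KO", "WT"):
        if (cond == label).sum() < 2:
            raise ValueError(f"need at least 2 samples for condition {label}")

    values = intensities.to_numpy(dtype=float)
    if np.nanmin(values) <= 0:
        raise ValueError("intensities must be strictly positive")
    logv = np.log(values)

    has_nan = np.isnan(values).any(axis=1)
    measurements: list[MetaboliteMeasurement] = []
    complete = ~has_nan
    p_all = np.full(len(intensities.index), np.nan)
    if complete.any():
        p_all[complete] = _two_way_anova_condition_p(
            logv[complete].T, cond, batch
        )
    if has_nan.any():
        warnings.warn(
            f"{int(has_nan.sum())} metabolites have missing values; using "
            "pairwise-complete samples",
            stacklevel=2,
        )
        for i in np.where(has_nan)[0]:
            mask = ~np.isnan(values[i])
            p_all[i] = _two_way_anova_condition_p(
                logv[i, mask].reshape(-1, 1), cond[mask], batch[mask]
            )[0]

    for i, mid in enumerate(intensities.index):
        mask = ~np.isnan(values[i])
        ko = logv[i, mask & (cond == "KO")] if has_nan[i] else logv[i, cond == "KO"]
        wt = logv[i, mask & (cond == "WT")] if has_nan[i] else logv[i, cond == "WT"]
        fold = float(np.exp(ko.mean() - wt.mean()))
        measurements.append(
            MetaboliteMeasurement(str(mid), fold_change=fold, p_value=float(p_all[i]))
        )
    return measurements


# ---------------------------------------------------------------------------
# exchange classification and bound rules
# ---------------------------------------------------------------------------


def classify_exchanges(
    model: MetabolicModel, fraction_of_optimum: float = 0.0
) -> list[ExchangeClass]:
    """FVA-based classification of exchange reactions.

    secretion-only: min ≥ 0 < max; uptake-only: min < 0 ≥ max;
    bidirectional: min < 0 < max; blocked: min ≈ max ≈ 0.
    Classification defaults to pure feasibility (fraction 0), since it
    precedes imposition of the metabolic objective.
    """
    ex_ids = [r.id for r in model.exchanges]
    ranges = run_fva(model, fraction_of_optimum=fraction_of_optimum,
                     reaction_ids=ex_ids)
    out = []
    for rng in ranges:
        lo, hi = rng.min_flux, rng.max_flux
        if lo >= -FVA_SIGN_TOL and hi > FVA_SIGN_TOL:
            cls = "secretion_only"
        elif hi <= FVA_SIGN_TOL and lo < -FVA_SIGN_TOL:
            cls = "uptake_only"
        elif lo < -FVA_SIGN_TOL and hi > FVA_SIGN_TOL:
            cls = "bidirectional"
        else:
            cls = "blocked"
        out.append(ExchangeClass(rng.reaction_id, cls, lo, hi))
    return out


def apply_fold_change_constraints(
    model: MetabolicModel,
    measurements: list[MetaboliteMeasurement],
    classes: list[ExchangeClass],
    alpha: float = 0.05,
    mapping: dict[str, str] | None = None,
    r1_fraction: float = 0.10,
    r2_fraction: float = 0.10,
    r3_fraction: float = 0.10,
    r4_fraction: float = 0.90,
    check_feasibility: bool = True,
) -> tuple[MetabolicModel, ConstraintLedger]:
    """Apply the four fold-change → bound rules to significant measurements.

    *mapping* translates measurement metabolite ids to model exchange
    reaction ids; without it the metabolite id must itself be an exchange
    id.  Each constrained exchange receives exactly one rule; bidirectional
    and blocked exchanges are logged untouched.  The constrained model's
    feasibility (FBA on its objective) is re-verified.
    """
    class_by_id = {c.exchange_reaction_id: c for c in classes}
    new_model = model.copy()
    ledger = ConstraintLedger()
    for meas in sorted(measurements, key=lambda m: m.metabolite_id):
        if meas.p_value >= alpha:
            continue
        if meas.fold_change == 1.0:
            continue
        ex_id = (mapping or {}).get(meas.metabolite_id, meas.metabolite_id)
        if ex_id not in class_by_id:
            ledger.skip(ex_id, f"{meas.metabolite_id}: no such exchange")
            logger.warning("measurement %s: no exchange %s", meas.metabolite_id, ex_id)
            continue
        cls = class_by_id[ex_id]
        rxn = new_model.reaction(ex_id)
        if cls.exchange_class in ("bidirectional", "blocked"):
            ledger.skip(ex_id, f"class {cls.exchange_class}: rules not applicable")
            continue
        up = meas.direction == "up"
        if up and cls.exchange_class == "secretion_only":
            new_lb = r1_fraction * cls.fva_max
            ledger.record(rxn, new_lb, rxn.upper_bound, "R1")
            rxn.lower_bound = new_lb
        elif up and cls.exchange_class == "uptake_only":
            new_lb = r2_fraction * cls.fva_min
            ledger.record(rxn, new_lb, rxn.upper_bound, "R2")
            rxn.lower_bound = new_lb
        elif not up and cls.exchange_class == "secretion_only":
            new_ub = r3_fraction * cls.fva_max
            ledger.record(rxn, rxn.lower_bound, new_ub, "R3")
            rxn.upper_bound = new_ub
        else:  # down, uptake_only
            new_ub = r4_fraction * cls.fva_min
            ledger.record(rxn, rxn.lower_bound, new_ub, "R4")
            rxn.upper_bound = new_ub
        if rxn.lower_bound > rxn.upper_bound:
            raise InfeasibleModelError(
                f"rule on {ex_id} inverted its bounds "
                f"[{rxn.lower_bound}, {rxn.upper_bound}]"
            )

    if check_feasibility and new_model.objective_id is not None:
        sol = solve_fba(new_model)
        if sol.status != "optimal":
            rules = [e.reaction_id + ":" + e.rule for e in ledger.entries]
            raise InfeasibleModelError(
                f"model infeasible after fold-change constraints {rules}"
            )
    return new_model, ledger


def set_reference_exchanges(
    model: MetabolicModel,
    mapped_metabolite_ids: list[str],
    reference_uptake: float = 0.25,
    free_ions: tuple[str, ...] = FREE_ION_METABOLITES,
    bound: float = 1000.0,
) -> tuple[MetabolicModel, ConstraintLedger]:
    """Reference uptake for measured substrates; free exchange for ions/water.

    Exchanges of the metabolites in *mapped_metabolite_ids* get a lower
    bound of −*reference_uptake* (0.25 mmol/gDW/h); exchanges whose single
    metabolite's base name is in *free_ions* get bounds [−bound, +bound].
    Unknown ids are skipped with a warning.
    """
    new_model = model.copy()
    ledger = ConstraintLedger()
    ex_by_met: dict[str, list] = {}
    for rxn in new_model.exchanges:
        (mid,) = rxn.stoichiometry
        base = mid.rsplit("_", 1)[0] if "_" in mid else mid
        ex_by_met.setdefault(mid, []).append(rxn)
        ex_by_met.setdefault(base, []).append(rxn)

    for ion in free_ions:
        for rxn in ex_by_met.get(ion, []):
            ledger.record(rxn, -bound, bound, "free_ion")
            rxn.lower_bound, rxn.upper_bound = -bound, bound

    free_set = set(free_ions)
    for mid in mapped_metabolite_ids:
        base = mid.rsplit("_", 1)[0] if "_" in mid else mid
        if base in free_set:
            continue
        rxns = ex_by_met.get(mid) or ex_by_met.get(base)
        if not rxns:
            warnings.warn(f"no exchange found for metabolite {mid!r}; skipped",
                          stacklevel=2)
            ledger.skip(mid, "no exchange for metabolite")
            continue
        for rxn in rxns:
            new_lb = -reference_uptake
            ledger.record(rxn, new_lb, rxn.upper_bound, "reference_uptake")
            rxn.lower_bound = new_lb
    return new_model, ledger


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def read_measurements_tsv(path: str) -> list[MetaboliteMeasurement]:
    """Measurements TSV: metabolite_id, fold_change, p_value."""
    frame = pd.read_csv(path, sep="\t")
    need = {"metabolite_id", "fold_change", "p_value"}
    if not need <= set(frame.columns):
        raise ValueError(f"measurements TSV needs columns {sorted(need)}")
    return [
        MetaboliteMeasurement(str(r.metabolite_id), float(r.fold_change),
                              float(r.p_value))
        for r in frame.itertuples()
    ]


def read_mapping_tsv(path: str) -> dict[str, str]:
    """Mapping TSV: measurement metabolite_id <tab> model exchange id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("mapping TSV needs metabolite_id and exchange_id columns")
    a, b = frame.columns[:2]
    return dict(zip(frame[a], frame[b]))
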