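"""End-to-end wildtype-vs-knockout pipeline.

Order of operations: replicate P/A consensus → (optional ortholog mapping)
→ GPR presence → GIMME penalties → metabolomic fold changes (two-way
ANOVA) → reference/free-ion exchange bounds → knockout planting → FVA
exchange classification → fold-change bound rules (KO model) → 10× reorder
ensemble GIMME per condition → flux sampling of each consensus submodel →
KS differential reactions and co-sets → model diff, subsystem breakdown
and metabolite-connectivity ranking of the condition-unique reaction sets.

Everything is deterministic given the master seed: per-stage seeds are
derived arithmetically from it, and all written reports are byte-stable
(sorted keys, fixed float formatting, no timestamps).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .compare import (
    ConnectivityReport,
    EnsembleResult,
    ModelDiff,
    SubsystemDiff,
    build_ensemble,
    diff_models,
    metabolite_connectivity,
    subsystem_breakdown,
)
from .constraints import (
    ConstraintLedger,
    MetaboliteMeasurement,
    apply_fold_change_constraints,
    classify_exchanges,
    compute_fold_changes,
    set_reference_exchanges,
)
from .gimme import (
    ExpressionCalls,
    OrthologTable,
    compute_penalties,
    consensus_presence,
    gpr_presence,
    map_orthologs,
)
from .model import MetabolicModel
from .sampling import (
    CoSet,
    DifferentialReaction,
    FluxSampleSet,
    compute_cosets,
    differential_reactions,
    normalize_samples,
    sample_fluxes,
)
from .synth import plant_knockout

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_reports"]


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05          # metabolomic significance cutoff
    required_fraction: float = 0.9
    n_runs: int = 10             # reorder-ensemble size per condition
    p_threshold: float = 0.001   # KS cutoff for differential reactions
    r_cutoff: float = 0.95       # Pearson cutoff for co-sets
    thinning: int = 100
    n_points: int | None = None  # sampling points; None -> 2n
    reference_uptake: float = 0.25
    knockout_exchange: str | None = "EX_urate_e"
    min_present: int = 2
    xcutoff: float = 0.5


@dataclass
class PipelineResult:
    config: PipelineConfig
    measurements: list[MetaboliteMeasurement]
    wt_model: MetabolicModel
    ko_model: MetabolicModel
    reference_ledger: ConstraintLedger
    constraint_ledger: ConstraintLedger
    wt_ensemble: EnsembleResult
    ko_ensemble: EnsembleResult
    wt_samples: FluxSampleSet
    ko_samples: FluxSampleSet
    differential: list[DifferentialReaction]
    wt_cosets: list[CoSet]
    ko_cosets: list[CoSet]
    diff: ModelDiff
    subsystems: SubsystemDiff
    connectivity_ko_unique: ConnectivityReport
    connectivity_wt_unique: ConnectivityReport


def run_pipeline(
    model: MetabolicModel,
    wt_calls: ExpressionCalls,
    ko_calls: ExpressionCalls,
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    mapping: dict[str, str],
    config: PipelineConfig | None = None,
    ortholog_table: OrthologTable | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Execute the full comparison pipeline; optionally write reports."""
    cfg = config or PipelineConfig()

    # --- expression evidence ---------------------------------------------
    def presence_of(calls: ExpressionCalls) -> dict[str, bool]:
        presence = consensus_presence(calls, min_present=cfg.min_present)
        if ortholog_table is not None:
            presence = map_orthologs(presence, ortholog_table, model.genes)
        return presence

    wt_presence = presence_of(wt_calls)
    ko_presence = presence_of(ko_calls)

    # --- metabolomic measurements ----------------------------------------
    measurements = compute_fold_changes(intensities, design)

    # --- exchange environment --------------------------------------------
    measured_ids = sorted(mapping)
    base, reference_ledger = set_reference_exchanges(
        model, measured_ids, reference_uptake=cfg.reference_uptake
    )
    wt_model = base
    ko_model = (
        plant_knockout(base, cfg.knockout_exchange)
        if cfg.knockout_exchange
        else base.copy()
    )
    # fold changes describe the KO state relative to WT: constrain KO only
    exchange_mapping = {mid: mapping[mid] for mid in mapping}
    classes = classify_exchanges(ko_model, fraction_of_optimum=0.0)
    ko_model, constraint_ledger = apply_fold_change_constraints(
        ko_model, measurements, classes, alpha=cfg.alpha, mapping=exchange_mapping
    )

    # --- context-specific model extraction (ensemble GIMME) ---------------
    wt_pen = compute_penalties(gpr_presence(wt_model, wt_presence), cfg.xcutoff)
    ko_pen = compute_penalties(gpr_presence(ko_model, ko_presence), cfg.xcutoff)
    wt_ensemble = build_ensemble(
        wt_model, wt_pen, n_runs=cfg.n_runs, base_seed=cfg.seed * 100,
        required_fraction=cfg.required_fraction,
    )
    ko_ensemble = build_ensemble(
        ko_model, ko_pen, n_runs=cfg.n_runs, base_seed=cfg.seed * 100 + cfg.n_runs,
        required_fraction=cfg.required_fraction,
    )

    # --- flux-space characterization --------------------------------------
    wt_sub = wt_model.subset(wt_ensemble.consensus_active)
    ko_sub = ko_model.subset(ko_ensemble.consensus_active)
    wt_samples = normalize_samples(
        sample_fluxes(wt_sub, n_points=cfg.n_points, seed=cfg.seed * 100 + 50,
                      thinning=cfg.thinning)
    )
    ko_samples = normalize_samples(
        sample_fluxes(ko_sub, n_points=cfg.n_points, seed=cfg.seed * 100 + 51,
                      thinning=cfg.thinning)
    )
    differential = differential_reactions(wt_samples, ko_samples,
                                          p_threshold=cfg.p_threshold)
    wt_cosets = compute_cosets(wt_samples, r_cutoff=cfg.r_cutoff)
    ko_cosets = compute_cosets(ko_samples, r_cutoff=cfg.r_cutoff)

    # --- comparison layer --------------------------------------------------
    diff = diff_models(wt_ensemble.consensus_active, ko_ensemble.consensus_active,
                       model)
    subsystems = subsystem_breakdown(diff, model)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # empty unique sets are a legitimate null outcome here
        _warnings.simplefilter("ignore", UserWarning)
        conn_ko = metabolite_connectivity(model, diff.unique_ko)
        conn_wt = metabolite_connectivity(model, diff.unique_wt)

    result = PipelineResult(
        config=cfg,
        measurements=measurements,
        wt_model=wt_model,
        ko_model=ko_model,
        reference_ledger=reference_ledger,
        constraint_ledger=constraint_ledger,
        wt_ensemble=wt_ensemble,
        ko_ensemble=ko_ensemble,
        wt_samples=wt_samples,
        ko_samples=ko_samples,
        differential=differential,
        wt_cosets=wt_cosets,
        ko_cosets=ko_cosets,
        diff=diff,
        subsystems=subsystems,
        connectivity_ko_unique=conn_ko,
        connectivity_wt_unique=conn_wt,
    )
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# deterministic report writing
# ---------------------------------------------------------------------------


def _write_tsv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 lineterminator="\n")


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_reports(result: PipelineResult, out_dir: str) -> None:
    """Write the full report bundle as TSV/JSON under *out_dir*.

    Reruns with identical inputs and seeds produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    j = os.path.join

    _write_tsv(
        pd.DataFrame(
            [{"metabolite_id": m.metabolite_id,
              "fold_change": m.fold_change,
              "p_value": m.p_value,
              "direction": m.direction}
             for m in sorted(result.measurements, key=lambda m: m.metabolite_id)]
        ),
        j(out_dir, "measurements.tsv"),
    )
    _write_tsv(result.reference_ledger.to_frame(), j(out_dir, "reference_ledger.tsv"))
    _write_tsv(result.constraint_ledger.to_frame(), j(out_dir, "constraint_ledger.tsv"))

    for label, ens in (("wt", result.wt_ensemble), ("ko", result.ko_ensemble)):
        _write_json(
            {"consensus_active": sorted(ens.consensus_active),
             "run_seeds": ens.run_seeds,
             "run_scores": ens.run_scores,
             "run_active_sizes": [len(s) for s in ens.run_active_sets]},
            j(out_dir, f"ensemble_{label}.json"),
        )

    _write_tsv(
        pd.DataFrame(
            [{"reaction_id": d.reaction_id, "ks_statistic": d.ks_statistic,
              "p_value": d.p_value, "direction": d.direction}
             for d in result.differential],
            columns=["reaction_id", "ks_statistic", "p_value", "direction"],
        ),
        j(out_dir, "differential_reactions.tsv"),
    )
    for label, cosets in (("wt", result.wt_cosets), ("ko", result.ko_cosets)):
        _write_tsv(
            pd.DataFrame(
                [{"coset": i, "members": ";".join(cs.members)}
                 for i, cs in enumerate(cosets)],
                columns=["coset", "members"],
            ),
            j(out_dir, f"cosets_{label}.tsv"),
        )

    _write_json(
        {"shared_reactions": sorted(result.diff.shared_reactions),
         "unique_wt": sorted(result.diff.unique_wt),
         "unique_ko": sorted(result.diff.unique_ko),
         "unique_wt_metabolites": sorted(result.diff.unique_wt_metabolites),
         "unique_ko_metabolites": sorted(result.diff.unique_ko_metabolites)},
        j(out_dir, "model_diff.json"),
    )
    _write_tsv(result.diff.compartment_counts.replace([np.inf], "inf"),
               j(out_dir, "compartment_counts.tsv"))
    _write_tsv(result.subsystems.table, j(out_dir, "subsystem_diff.tsv"))

    for label, conn in (("ko_unique", result.connectivity_ko_unique),
                        ("wt_unique", result.connectivity_wt_unique)):
        _write_tsv(
            pd.DataFrame(
                [{"metabolite_id": mid, "connectivity": conn.cm[mid]}
                 for mid in conn.ranking],
            ),
            j(out_dir, f"connectivity_{label}.tsv"),
        )

    _write_json(
        {
            "config": asdict(result.config),
            "wt_score_mean": float(np.mean(result.wt_ensemble.run_scores)),
            "ko_score_mean": float(np.mean(result.ko_ensemble.run_scores)),
            "n_shared": len(result.diff.shared_reactions),
            "n_unique_wt": len(result.diff.unique_wt),
            "n_unique_ko": len(result.diff.unique_ko),
            "n_differential": len(result.differential),
            "top_connectivity_ko_unique": result.connectivity_ko_unique.top(10),
            "sampling_seeds": [result.wt_samples.seed, result.ko_samples.seed],
        },
        j(out_dir, "summary.json"),
    )
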