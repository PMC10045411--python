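"""Wildtype-vs-knockout comparison layer.

Covers the ensemble-robust context-specific model construction (GIMME rerun
on 10 random reaction reorderings, reporting only reactions shared by all
runs), reaction/metabolite set differences with per-compartment counts,
the per-subsystem breakdown of unique reactions, and the metabolite
connectivity ranking cm = diag(Sb·SbT) that surfaces redox cofactors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gimme import GimmeResult, PenaltyVector, run_gimme
from .lp import InfeasibleModelError
from .model import MetabolicModel, binarize, build_stoichiometric_matrix

__all__ = [
    "EnsembleResult",
    "ModelDiff",
    "SubsystemDiff",
    "ConnectivityReport",
    "build_ensemble",
    "diff_models",
    "subsystem_breakdown",
    "metabolite_connectivity",
]

logger = logging.getLogger(__name__)


@dataclass
class EnsembleResult:
    run_active_sets: list[set[str]]
    consensus_active: set[str]
    run_seeds: list[int]
    run_orders: list[list[int]]
    run_scores: list[float]


@dataclass
class ModelDiff:
    shared_reactions: set[str]
    unique_wt: set[str]
    unique_ko: set[str]
    shared_metabolites: set[str]
    unique_wt_metabolites: set[str]
    unique_ko_metabolites: set[str]
    compartment_counts: pd.DataFrame  # compartment × (wt, ko, ratio)


@dataclass
class SubsystemDiff:
    table: pd.DataFrame  # subsystem × (unique_wt, unique_ko, size, fraction)


@dataclass
class ConnectivityReport:
    cm: dict[str, int]
    reaction_subset: list[str]
    ranking: list[str]  # metabolite ids, descending cm, ties lexicographic

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]


def build_ensemble(
    model: MetabolicModel,
    penalties: PenaltyVector,
    n_runs: int = 10,
    base_seed: int = 0,
    required_fraction: float = 0.9,
) -> EnsembleResult:
    """Rerun GIMME on seeded random reaction reorderings and intersect.

    Run i permutes the reaction (LP column) order with seed base_seed + i,
    reruns GIMME, and records the active set; the consensus is the strict
    intersection across all runs.  Any infeasible run raises, naming its
    seed.
    """
    active_sets: list[set[str]] = []
    seeds: list[int] = []
    orders: list[list[int]] = []
    scores: list[float] = []
    n = len(model.reactions)
    for i in range(n_runs):
        seed = base_seed + i
        order = list(np.random.default_rng(seed).permutation(n))
        permuted = model.reorder_reactions(order)
        try:
            result = run_gimme(permuted, penalties, required_fraction)
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(f"ensemble run seed {seed}: {exc}") from exc
        active_sets.append(result.active_reactions)
        seeds.append(seed)
        orders.append(order)
        scores.append(result.inconsistency_score)
    consensus = set.intersection(*active_sets) if active_sets else set()
    return EnsembleResult(active_sets, consensus, seeds, orders, scores)


def _metabolites_of(model: MetabolicModel, reaction_ids: set[str]) -> set[str]:
    mets: set[str] = set()
    for rid in reaction_ids:
        mets |= set(model.reaction(rid).stoichiometry)
    return mets


def diff_models(
    wt_active: set[str], ko_active: set[str], model: MetabolicModel
) -> ModelDiff:
    """Partition active reactions into shared / unique-WT / unique-KO and
    derive the induced metabolite sets with per-compartment KO/WT ratios
    (0/0 → 1.0; x/0 → inf, flagged)."""
    known = set(model.reaction_ids)
    for name, s in (("wt_active", wt_active), ("ko_active", ko_active)):
        extra = s - known
        if extra:
            raise ValueError(f"{name} contains unknown reactions: {sorted(extra)[:5]}")
    shared = wt_active & ko_active
    uw = wt_active - ko_active
    uk = ko_active - wt_active

    wt_mets = _metabolites_of(model, wt_active)
    ko_mets = _metabolites_of(model, ko_active)
    compartments = sorted(
        {model.metabolite(m).compartment for m in (wt_mets | ko_mets)}
    )
    rows = []
    for comp in compartments:
        n_wt = sum(1 for m in wt_mets if model.metabolite(m).compartment == comp)
        n_ko = sum(1 for m in ko_mets if model.metabolite(m).compartment == comp)
        if n_wt == 0 and n_ko == 0:
            ratio = 1.0
        elif n_wt == 0:
            ratio = float("inf")
            logger.warning("compartment %s: KO/WT ratio infinite (%d/0)", comp, n_ko)
        else:
            ratio = n_ko / n_wt
        rows.append({"compartment": comp, "wt": n_wt, "ko": n_ko, "ratio": ratio})
    return ModelDiff(
        shared_reactions=shared,
        unique_wt=uw,
        unique_ko=uk,
        shared_metabolites=wt_mets & ko_mets,
        unique_wt_metabolites=wt_mets - ko_mets,
        unique_ko_metabolites=ko_mets - wt_mets,
        compartment_counts=pd.DataFrame(rows, columns=["compartment", "wt", "ko", "ratio"]),
    )


def subsystem_breakdown(diff: ModelDiff, model: MetabolicModel) -> SubsystemDiff:
    """Unique-reaction counts per subsystem plus the fraction of the
    subsystem affected (to counter subsystem-size bias).  Unlabeled
    reactions are grouped under "unassigned"."""
    sub_of = {
        r.id: (r.subsystem or "unassigned") for r in model.reactions
    }
    sizes: dict[str, int] = {}
    for r in model.reactions:
        sizes[sub_of[r.id]] = sizes.get(sub_of[r.id], 0) + 1
    counts: dict[str, dict[str, int]] = {
        s: {"unique_wt": 0, "unique_ko": 0} for s in sizes
    }
    for rid in diff.unique_wt:
        counts[sub_of[rid]]["unique_wt"] += 1
    for rid in diff.unique_ko:
        counts[sub_of[rid]]["unique_ko"] += 1
    rows = []
    for sub in sorted(sizes):
        uw, uk = counts[sub]["unique_wt"], counts[sub]["unique_ko"]
        rows.append(
            {"subsystem": sub, "unique_wt": uw, "unique_ko": uk,
             "size": sizes[sub], "fraction": (uw + uk) / sizes[sub]}
        )
    table = pd.DataFrame(
        rows, columns=["subsystem", "unique_wt", "unique_ko", "size", "fraction"]
    )
    return SubsystemDiff(table=table)


def metabolite_connectivity(
    model: MetabolicModel, reaction_subset: list[str] | set[str]
) -> ConnectivityReport:
    """Metabolite connectivity cm = diag(Sb·SbT) over a reaction subset.

    The stoichiometric matrix is binarized, all columns outside
    *reaction_subset* are zeroed, and cm[i] counts the subset reactions
    whose stoichiometry involves metabolite i.  The ranking is by
    descending cm with lexicographic tie-break on metabolite id.
    """
    subset = sorted(set(reaction_subset))
    unknown = set(subset) - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"unknown reactions in subset: {sorted(unknown)[:5]}")
    if not subset:
        warnings.warn("empty reaction subset: connectivity is identically zero",
                      stacklevel=2)
    Sb = binarize(build_stoichiometric_matrix(model)).values
    col_index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    mask = np.zeros(Sb.shape[1])
    for rid in subset:
        mask[col_index[rid]] = 1.0
    Sb = Sb * mask[None, :]
    cm_values = np.diag(Sb @ Sb.T).astype(int)
    cm = {mid: int(cm_values[i]) for i, mid in enumerate(model.metabolite_ids)}
    ranking = sorted(cm, key=lambda m: (-cm[m], m))
    return ConnectivityReport(cm=cm, reaction_subset=subset, ranking=ranking)
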