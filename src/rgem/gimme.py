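"""Context-specific subnetwork extraction with the GIMME linear program.

Expression evidence enters as Affymetrix-style present/absent (P/A) calls.
Replicates are collapsed by a 2-of-3 consensus rule (a gene is present iff
called present in at least ``min_present`` replicates), optionally pushed
through a source→target ortholog table, and mapped onto reactions through
GPR logic (OR = any operand present, AND = all operands present).

The extraction itself minimizes the total penalized flux

    min  Σ_j c_j |v_j|    s.t.  S·v = 0,  vl ≤ v ≤ vu,
                                 v_obj ≥ required_fraction × v_obj*

where the weight c_j = max(x_cutoff − x_j, 0) is positive only for
below-cutoff (absent) reactions.  With binary P/A evidence x ∈ {0, 1} and
x_cutoff = 0.5, every absent reaction carries the same penalty 0.5; any
positive constant gives the same argmin and active set.  The absolute value
is linearized by the nonnegative split v = v+ − v−, and the optimal value
of the LP is the model's inconsistency score (0 = the expression data and
the required metabolic functionality are fully compatible).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .lp import (
    FluxDistribution,
    InfeasibleModelError,
    _STATUS,
    _lp,
    solve_fba,
    split_reversible,
)
from .model import MetabolicModel, build_stoichiometric_matrix, eval_gpr

__all__ = [
    "ExpressionCalls",
    "OrthologTable",
    "PenaltyVector",
    "GimmeResult",
    "consensus_presence",
    "map_orthologs",
    "gpr_presence",
    "compute_penalties",
    "run_gimme",
    "read_expression_tsv",
    "read_ortholog_tsv",
]

logger = logging.getLogger(__name__)

ACTIVE_FLUX_TOL = 1e-6


@dataclass
class ExpressionCalls:
    """Per-replicate P/A calls: boolean DataFrame (genes × replicates),
    True = present."""

    calls: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)


@dataclass
class OrthologTable:
    """Many-to-one source-gene → target-gene mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        empty = [s for s, t in self.mapping.items() if not t]
        if empty:
            raise ValueError(f"ortholog table has empty targets for {sorted(empty)}")


@dataclass
class PenaltyVector:
    """GIMME weights c = max(x_cutoff − x, 0) per reaction."""

    c: dict[str, float]
    x: dict[str, float]
    xcutoff: float = 0.5

    def __post_init__(self) -> None:
        bad = {r: w for r, w in self.c.items() if w < 0}
        if bad:
            raise ValueError(f"negative penalties: {bad}")


@dataclass
class GimmeResult:
    active_reactions: set[str]
    inconsistency_score: float
    flux_solution: FluxDistribution
    required_fraction: float


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------


def consensus_presence(
    calls: ExpressionCalls | pd.DataFrame, min_present: int = 2
) -> dict[str, bool]:
    """Collapse replicate P/A calls: present iff ≥ *min_present* replicates
    call the gene present.  Missing (NaN) entries count as absent calls."""
    frame = calls.calls if isinstance(calls, ExpressionCalls) else calls
    if frame.shape[1] < min_present:
        raise ValueError(
            f"need at least min_present={min_present} replicates, got {frame.shape[1]}"
        )
    if frame.isna().any().any():
        missing = frame.index[frame.isna().any(axis=1)]
        logger.warning(
            "%d genes missing in some replicate; treated as absent there",
            len(missing),
        )
        frame = frame.astype("boolean").fillna(False).astype(bool)
    counts = frame.astype(bool).sum(axis=1)
    return {gene: bool(counts[gene] >= min_present) for gene in frame.index}


def map_orthologs(
    presence: dict[str, bool],
    table: OrthologTable,
    model_genes: set[str] | None = None,
) -> dict[str, bool]:
    """Project source-gene presence onto target genes.

    A target gene is present iff *any* source gene mapping to it is present
    (many-to-one rule).  Model genes with no incoming mapping are reported
    via warning and omitted from the result.
    """
    out: dict[str, bool] = {}
    for source, called in presence.items():
        target = table.mapping.get(source)
        if target is None:
            continue
        if called and not out.get(target, False):
            logger.debug("ortholog %s -> %s: present", source, target)
        out[target] = out.get(target, False) or called
    if model_genes is not None:
        unmapped = sorted(model_genes - set(out))
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} model genes have no ortholog mapping: "
                f"{unmapped[:10]}{'...' if len(unmapped) > 10 else ''}",
                stacklevel=2,
            )
    return out


def gpr_presence(
    model: MetabolicModel, gene_presence: dict[str, bool]
) -> dict[str, str]:
    """Evaluate each reaction's GPR against gene presence.

    Returns reaction → {"present", "absent", "no_gpr"}.  Reactions without
    a GPR carry no evidence and are never penalized downstream.
    """
    out: dict[str, str] = {}
    for rxn in model.reactions:
        state = eval_gpr(rxn.gpr, gene_presence, default=False)
        if state is None:
            out[rxn.id] = "no_gpr"
        else:
            out[rxn.id] = "present" if state else "absent"
    return out


def compute_penalties(
    reaction_presence: dict[str, str], xcutoff: float = 0.5
) -> PenaltyVector:
    """Binary expression encoding: x = 1 for present/no_gpr, 0 for absent;
    c = max(xcutoff − x, 0), i.e. c = xcutoff for absent reactions only."""
    x = {
        rid: (0.0 if state == "absent" else 1.0)
        for rid, state in reaction_presence.items()
    }
    c = {rid: max(xcutoff - xi, 0.0) for rid, xi in x.items()}
    return PenaltyVector(c=c, x=x, xcutoff=xcutoff)


# ---------------------------------------------------------------------------
# the GIMME LP
# ---------------------------------------------------------------------------


def run_gimme(
    model: MetabolicModel,
    penalties: PenaltyVector,
    required_fraction: float = 0.9,
    objective_id: str | None = None,
) -> GimmeResult:
    """Solve the GIMME LP and extract the context-specific active set.

    active_reactions = unpenalized reactions ∪ penalized reactions carrying
    |v*| > 1e-6 in the optimum.  The inconsistency score is the optimal
    Σ c_j |v_j|; infeasibility after adding the functionality constraint is
    an error, never silently relaxed.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("run_gimme: model has no objective reaction")
    if not 0.0 <= required_fraction <= 1.0:
        raise ValueError("required_fraction must lie in [0, 1]")

    opt = solve_fba(model, objective_id)
    if opt.status != "optimal":
        raise InfeasibleModelError(f"objective FBA is {opt.status}")
    if opt.objective_value <= ACTIVE_FLUX_TOL:
        warnings.warn(
            f"objective optimum is {opt.objective_value:.3g}; the "
            "required-fraction constraint is vacuous",
            stacklevel=2,
        )

    split = split_reversible(model)
    S = build_stoichiometric_matrix(model).values
    rxn_index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    ncol = len(split.columns)

    A_eq = np.empty((S.shape[0], ncol))
    cvec = np.empty(ncol)
    obj_row = np.zeros(ncol)
    for k, (rid, sign) in enumerate(split.columns):
        j = rxn_index[rid]
        A_eq[:, k] = sign * S[:, j]
        cvec[k] = penalties.c.get(rid, 0.0)
        if rid == objective_id:
            obj_row[k] = -sign
    b_eq = np.zeros(S.shape[0])
    A_ub = obj_row.reshape(1, -1)
    b_ub = np.array([-required_fraction * opt.objective_value])

    res = _lp(cvec, sparse.csr_matrix(A_eq), b_eq, split.bounds, A_ub=A_ub, b_ub=b_ub)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        raise InfeasibleModelError(
            f"GIMME LP is {status} at required_fraction={required_fraction}"
        )

    fluxes = split.fold(res.x)
    score = float(res.fun)
    active = {
        rid
        for rid in model.reaction_ids
        if penalties.c.get(rid, 0.0) == 0.0 or abs(fluxes[rid]) > ACTIVE_FLUX_TOL
    }
    sol = FluxDistribution(fluxes, float(fluxes[objective_id]), "optimal")
    return GimmeResult(
        active_reactions=active,
        inconsistency_score=score,
        flux_solution=sol,
        required_fraction=required_fraction,
    )


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str, condition: str = "") -> ExpressionCalls:
    """Expression TSV: gene_id column + one P/A column per replicate."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    calls = frame.apply(lambda col: col.astype(str).str.upper().eq("P"))
    return ExpressionCalls(calls=calls, condition=condition)


def write_expression_tsv(calls: ExpressionCalls, path: str) -> None:
    out = calls.calls.replace({True: "P", False: "A"})
    out.to_csv(path, sep="\t")


def read_ortholog_tsv(path: str) -> OrthologTable:
    """Ortholog TSV: source_id <tab> target_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("ortholog TSV needs source_id and target_id columns")
    src, tgt = frame.columns[:2]
    return OrthologTable(mapping=dict(zip(frame[src], frame[tgt])))
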