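"""Uniform sampling of the steady-state flux polytope and sample-level
statistics: differentially active reactions (two-sample KS) and correlated
reaction sets (co-sets).

The sampler is artificial-centering hit-and-run (ACHR): warmup points are
the FVA extreme-point solutions, search directions are differences between
a randomly chosen stored point and the running center (hence automatically
inside the null space of S), and the step length is drawn uniformly over
the feasible chord.  One point is kept every ``thinning`` steps and
re-projected onto the null space to suppress numerical drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lp import InfeasibleModelError, run_fva
from .model import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "FluxSampleSet",
    "DifferentialReaction",
    "CoSet",
    "sample_fluxes",
    "normalize_samples",
    "differential_reactions",
    "compute_cosets",
]

logger = logging.getLogger(__name__)

DIRECTION_TOL = 1e-9
FLAT_TOL = 1e-9
MIN_SAMPLES_PER_SIDE = 8


@dataclass
class FluxSampleSet:
    """Matrix of sampled feasible flux states (n_points × n_reactions)."""

    samples: np.ndarray
    reaction_ids: list[str]
    seed: int
    n_points: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.reaction_ids):
            raise ValueError("FluxSampleSet: shape/id mismatch")

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)


@dataclass
class DifferentialReaction:
    reaction_id: str
    ks_statistic: float
    p_value: float
    direction: int  # sign of mean(KO) − mean(WT)


@dataclass
class CoSet:
    members: list[str]


def sample_fluxes(
    model: MetabolicModel,
    n_points: int | None = None,
    seed: int = 0,
    thinning: int = 100,
    warmup: np.ndarray | None = None,
) -> FluxSampleSet:
    """ACHR-sample the flux polytope {S·v = 0, vl ≤ v ≤ vu}.

    ``n_points`` defaults to 2n for n model reactions.  A numerically flat
    polytope (all FVA widths < 1e-9) yields a single-point set with a
    warning.  Identical seeds give bit-identical sample sets.  A
    precomputed FVA *warmup* point matrix (as produced by
    ``run_fva(..., return_points=True)``) may be passed to amortize the
    warmup cost over repeated samplings of the same model.
    """
    n = len(model.reactions)
    if n_points is None:
        n_points = 2 * n
    if warmup is None:
        ranges, warmup = run_fva(model, fraction_of_optimum=0.0, return_points=True)
        widths = np.array([r.max_flux - r.min_flux for r in ranges])
    else:
        warmup = np.asarray(warmup, dtype=float)
        widths = warmup.max(axis=0) - warmup.min(axis=0)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    S = build_stoichiometric_matrix(model).values
    # orthogonal projector onto null(S) for drift control
    if S.size:
        u, s, vt = np.linalg.svd(S, full_matrices=True)
        rank = int(np.sum(s > max(S.shape) * np.finfo(float).eps * (s[0] if s.size else 1)))
        N = vt[rank:].T  # n × d null-space basis
        proj = N @ N.T
    else:
        proj = np.eye(n)

    if np.all(widths < FLAT_TOL):
        warnings.warn("flux polytope is numerically flat; returning a single point",
                      stacklevel=2)
        return FluxSampleSet(warmup[:1].copy(), model.reaction_ids, seed, 1)

    rng = np.random.default_rng(seed)
    stored = warmup.copy()
    center = stored.mean(axis=0)
    x = center.copy()
    n_stored = stored.shape[0]
    kept = np.empty((n_points, n))
    total_seen = n_stored

    for k in range(n_points):
        for _ in range(thinning):
            pick = stored[rng.integers(len(stored))]
            d = pick - center
            norm = np.linalg.norm(d)
            if norm < DIRECTION_TOL:
                continue
            d /= norm
            movable = np.abs(d) > DIRECTION_TOL
            if not movable.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lb - x) / d
                t_hi = (ub - x) / d
            lower = np.where(d > 0, t_lo, t_hi)[movable]
            upper = np.where(d > 0, t_hi, t_lo)[movable]
            t_min = lower.max()
            t_max = upper.min()
            if t_max - t_min < DIRECTION_TOL:
                continue
            t = rng.uniform(t_min, t_max)
            x = x + t * d
            total_seen += 1
            center = center + (x - center) / total_seen
        x = proj @ x
        np.clip(x, lb, ub, out=x)
        kept[k] = x
        stored = np.vstack([stored, x[None, :]])
    return FluxSampleSet(kept, model.reaction_ids, seed, n_points)


def normalize_samples(sample_set: FluxSampleSet) -> FluxSampleSet:
    """Scale each sampled flux state by its total absolute flux (L1 norm),
    making cross-model comparisons scale-free.  All-zero rows stay zero."""
    if sample_set.samples.size == 0:
        raise ValueError("normalize_samples: empty sample set")
    totals = np.abs(sample_set.samples).sum(axis=1, keepdims=True)
    scale = np.where(totals > 0, totals, 1.0)
    return FluxSampleSet(
        sample_set.samples / scale,
        list(sample_set.reaction_ids),
        sample_set.seed,
        sample_set.n_points,
    )


def differential_reactions(
    wt: FluxSampleSet,
    ko: FluxSampleSet,
    p_threshold: float = 0.001,
) -> list[DifferentialReaction]:
    """Two-sample KS test per reaction shared between the WT and KO sets.

    Returns reactions with p < *p_threshold*, sorted by descending KS
    statistic (no multiple-testing correction, by design).  Reactions with
    fewer than 8 samples on either side are skipped with a warning.
    """
    shared = [rid for rid in wt.reaction_ids if rid in set(ko.reaction_ids)]
    out: list[DifferentialReaction] = []
    for rid in shared:
        a = wt.column(rid)
        b = ko.column(rid)
        if len(a) < MIN_SAMPLES_PER_SIDE or len(b) < MIN_SAMPLES_PER_SIDE:
            warnings.warn(f"{rid}: fewer than {MIN_SAMPLES_PER_SIDE} samples; skipped",
                          stacklevel=2)
            continue
        ks = stats.ks_2samp(a, b, method="auto")
        if ks.pvalue < p_threshold:
            out.append(
                DifferentialReaction(
                    rid,
                    ks_statistic=float(ks.statistic),
                    p_value=float(ks.pvalue),
                    direction=int(np.sign(b.mean() - a.mean())),
                )
            )
    out.sort(key=lambda d: (-d.ks_statistic, d.reaction_id))
    return out


def compute_cosets(
    sample_set: FluxSampleSet,
    r_cutoff: float = 0.95,
    variance_tol: float = 1e-12,
) -> list[CoSet]:
    """Correlated reaction sets from sampled flux states.

    Reactions with sample variance < *variance_tol* are excluded; the
    remaining reactions form a graph with an edge where |Pearson r| ≥
    *r_cutoff*; co-sets are connected components of size ≥ 2 (single
    linkage), returned disjoint, each sorted, ordered by first member.
    """
    if sample_set.samples.shape[0] < 10:
        raise ValueError("compute_cosets: need at least 10 samples")
    variances = sample_set.samples.var(axis=0)
    keep = np.where(variances >= variance_tol)[0]
    if len(keep) < 2:
        return []
    X = sample_set.samples[:, keep]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    g = nx.Graph()
    g.add_nodes_from(range(len(keep)))
    ii, jj = np.where(np.triu(np.abs(corr) >= r_cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    cosets = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            cosets.append(
                CoSet(sorted(sample_set.reaction_ids[keep[i]] for i in comp))
            )
    cosets.sort(key=lambda cs: cs.members[0])
    return cosets
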