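"""Flux-balance analysis, flux-variability analysis and the nonnegative
split-variable reformulation.

All linear programs run through SciPy's HiGHS interface with simplex-grade
tolerances (1e-9), so optimal solutions are deterministic polytope vertices.
Objective values are unique even when the optimal flux vector is degenerate;
callers should therefore assert objective values and flux *ranges*, never a
specific alternate optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_matrix,
)

__all__ = [
    "FluxDistribution",
    "FluxRange",
    "SplitModel",
    "InfeasibleModelError",
    "solve_fba",
    "split_reversible",
    "run_fva",
]

FEAS_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """Raised when a constraint set admits no feasible flux."""


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": FEAS_TOL},
    )
    return res


def _model_arrays(model: MetabolicModel):
    S = build_stoichiometric_matrix(model)
    A_eq = sparse.csr_matrix(S.values)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return A_eq, b_eq, bounds


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Optimize flux through one reaction subject to S·v = 0 and bounds.

    Infeasibility and unboundedness are reported in ``status`` (with
    ``objective_value = nan``), never as silent zeros.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    j = model.reaction_ids.index(objective_id)
    A_eq, b_eq, bounds = _model_arrays(model)
    c = np.zeros(len(bounds))
    c[j] = -1.0 if sense == "max" else 1.0
    res = _lp(c, A_eq, b_eq, bounds)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution({}, float("nan"), status)
    fluxes = dict(zip(model.reaction_ids, map(float, res.x)))
    return FluxDistribution(fluxes, float(fluxes[objective_id]), "optimal")


# ---------------------------------------------------------------------------
# split-variable (v = v+ - v-) reformulation
# ---------------------------------------------------------------------------


@dataclass
class SplitModel:
    """Column pairing for the nonnegative reformulation v = v+ − v−.

    ``columns`` lists (reaction_id, sign) with sign +1 for the forward and
    −1 for the reverse column; the reverse column is absent when the
    reaction's lower bound is nonnegative.  ``bounds`` are the per-column
    (lb, ub) with 0 ≤ v+ ≤ vu and 0 ≤ v− ≤ −vl.
    """

    model: MetabolicModel
    columns: list[tuple[str, int]]
    bounds: list[tuple[float, float]]

    def to_model(self) -> MetabolicModel:
        """Materialize the split system as a model (for equivalence checks)."""
        rxns = []
        for (rid, sign), (lb, ub) in zip(self.columns, self.bounds):
            base = self.model.reaction(rid)
            stoich = dict(base.stoichiometry)
            rid_out = rid
            if sign < 0:
                stoich = {m: -c for m, c in stoich.items()}
                rid_out = rid + "_rev"
            rxns.append(
                Reaction(rid_out, stoich, lb, ub, base.gpr, base.subsystem, base.name)
            )
        mets = [
            Metabolite(m.id, m.name, m.compartment, m.formula, m.charge)
            for m in self.model.metabolites
        ]
        return MetabolicModel(mets, rxns, objective_id=self.model.objective_id,
                              id=self.model.id + "_split")

    def fold(self, x: np.ndarray) -> dict[str, float]:
        """Map a split-space point back to net fluxes v = v+ − v−."""
        v = {rid: 0.0 for rid in self.model.reaction_ids}
        for (rid, sign), xi in zip(self.columns, x):
            v[rid] += sign * float(xi)
        return v


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Split every reaction into nonnegative forward/reverse columns.

    Infinite bounds are rejected: cap them (convention ±1000 mmol/gDW/h)
    before splitting so 0 ≤ v− ≤ −vl is well defined.
    """
    columns: list[tuple[str, int]] = []
    bounds: list[tuple[float, float]] = []
    for rxn in model.reactions:
        if not (np.isfinite(rxn.lower_bound) and np.isfinite(rxn.upper_bound)):
            raise ValueError(
                f"reaction {rxn.id!r} has infinite bounds; cap them first "
                f"(default ±{DEFAULT_BOUND:g} mmol/gDW/h)"
            )
        if rxn.upper_bound > 0 or rxn.lower_bound >= 0:
            columns.append((rxn.id, +1))
            bounds.append((max(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0)))
        if rxn.lower_bound < 0:
            columns.append((rxn.id, -1))
            bounds.append((max(-rxn.upper_bound, 0.0), -rxn.lower_bound))
    return SplitModel(model, columns, bounds)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


def run_fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 0.0,
    reaction_ids: list[str] | None = None,
    return_points: bool = False,
):
    """Per-reaction flux minima/maxima under S·v = 0, bounds, and (for
    fraction > 0) objective ≥ fraction × FBA optimum.

    With ``return_points=True`` also returns the optimizing flux vectors
    (the classic warmup set for hit-and-run sampling) as an array of shape
    (2 × len(reaction_ids), n_reactions).
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    rids = reaction_ids if reaction_ids is not None else model.reaction_ids
    all_ids = model.reaction_ids
    index = {rid: j for j, rid in enumerate(all_ids)}
    A_eq, b_eq, bounds = _model_arrays(model)
    n = len(all_ids)

    A_ub = b_ub = None
    if fraction_of_optimum > 0:
        opt = solve_fba(model)
        if opt.status != "optimal":
            raise InfeasibleModelError(
                f"FVA: FBA on objective {model.objective_id!r} is {opt.status}"
            )
        row = np.zeros(n)
        row[index[model.objective_id]] = -1.0
        A_ub = row.reshape(1, -1)
        b_ub = np.array([-fraction_of_optimum * opt.objective_value])

    ranges: list[FluxRange] = []
    points = np.empty((2 * len(rids), n)) if return_points else None
    for k, rid in enumerate(rids):
        j = index[rid]
        lo_hi = []
        for s, sign in enumerate((1.0, -1.0)):  # min first, then max
            c = np.zeros(n)
            c[j] = sign
            res = _lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
            if _STATUS.get(res.status) != "optimal":
                raise InfeasibleModelError(
                    f"FVA on {rid!r}: {_STATUS.get(res.status, 'numerical')}"
                )
            lo_hi.append(float(res.x[j]))
            if return_points:
                points[2 * k + s] = res.x
        ranges.append(FluxRange(rid, min_flux=lo_hi[0], max_flux=lo_hi[1]))
    if return_points:
        return ranges, points
    return ranges


def fva_frame(ranges: list[FluxRange]):
    """FVA result as a pandas DataFrame (reaction_id, min, max) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {"reaction_id": [r.reaction_id for r in ranges],
         "min": [r.min_flux for r in ranges],
         "max": [r.max_flux for r in ranges]}
    )
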