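"""Brute-force oracles for flux polytopes, independent of the LP engine.

The steady-state flux set {v : S v = 0, lb <= v <= ub, (optional)
v_obj >= f * opt} is a polytope.  Working in null-space coordinates
(v = N y), every linear objective attains its optimum at a vertex, and
every piecewise-linear convex objective such as sum_j c_j |v_j| attains
its minimum at a vertex of the arrangement obtained by adding the
coordinate hyperplanes {v_j = 0}.  Both are enumerated exhaustively:
choose d = dim(null space) hyperplanes, solve the d x d system, keep
feasible points.  Only viable for tiny networks (n <= ~10).
"""

from __future__ import annotations

import itertools

import numpy as np

from rgem.model import MetabolicModel, build_stoichiometric_matrix

FEAS_TOL = 1e-7


def _null_space(S: np.ndarray) -> np.ndarray:
    if S.size == 0:
        return np.eye(S.shape[1])
    u, s, vt = np.linalg.svd(S, full_matrices=True)
    tol = max(S.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    rank = int(np.sum(s > tol))
    return vt[rank:].T  # n x d


def _facet_rows(model: MetabolicModel, N: np.ndarray,
                objective_floor: tuple[str, float] | None,
                zero_planes: bool):
    """All hyperplane (row, rhs) pairs and the feasibility predicate."""
    n, d = N.shape
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    rows, rhss = [], []
    for j in range(n):
        rows.append(N[j]); rhss.append(lb[j])
        rows.append(N[j]); rhss.append(ub[j])
        if zero_planes:
            rows.append(N[j]); rhss.append(0.0)
    floor_row = floor_rhs = None
    if objective_floor is not None:
        rid, floor = objective_floor
        jobj = model.reaction_ids.index(rid)
        floor_row, floor_rhs = N[jobj], floor
        rows.append(floor_row); rhss.append(floor_rhs)

    def feasible(y: np.ndarray) -> bool:
        v = N @ y
        if np.any(v < lb - FEAS_TOL) or np.any(v > ub + FEAS_TOL):
            return False
        if floor_row is not None and floor_row @ y < floor_rhs - FEAS_TOL:
            return False
        return True

    return rows, rhss, feasible


def enumerate_vertices(
    model: MetabolicModel,
    objective_floor: tuple[str, float] | None = None,
    zero_planes: bool = False,
) -> np.ndarray:
    """All vertices of the (optionally refined) flux polytope, as flux
    vectors (rows).  Returns an empty array if the polytope is empty."""
    S = build_stoichiometric_matrix(model).values
    N = _null_space(S)
    d = N.shape[1]
    rows, rhss, feasible = _facet_rows(model, N, objective_floor, zero_planes)
    points = []
    if d == 0:
        y = np.zeros(0)
        if feasible(y):
            points.append(N @ y)
    else:
        A_all = np.array(rows)
        b_all = np.array(rhss)
        for combo in itertools.combinations(range(len(rows)), d):
            A = A_all[list(combo)]
            b = b_all[list(combo)]
            if abs(np.linalg.det(A)) < 1e-10:
                continue
            y = np.linalg.solve(A, b)
            if feasible(y):
                points.append(N @ y)
    if not points:
        return np.empty((0, len(model.reactions)))
    return np.unique(np.round(np.array(points), 9), axis=0)


def oracle_max_objective(model: MetabolicModel, objective_id: str) -> float:
    """FBA oracle: maximum of one flux over all polytope vertices."""
    verts = enumerate_vertices(model)
    if verts.shape[0] == 0:
        raise ValueError("empty polytope")
    j = model.reaction_ids.index(objective_id)
    return float(verts[:, j].max())


def oracle_min_weighted_abs_flux(
    model: MetabolicModel,
    weights: dict[str, float],
    required_fraction: float,
    optimum: float,
) -> float:
    """GIMME oracle: minimum of sum_j c_j |v_j| over the polytope refined
    with the objective floor and the coordinate hyperplanes."""
    floor = (model.objective_id, required_fraction * optimum)
    verts = enumerate_vertices(model, objective_floor=floor, zero_planes=True)
    if verts.shape[0] == 0:
        raise ValueError("empty polytope under objective floor")
    c = np.array([weights.get(rid, 0.0) for rid in model.reaction_ids])
    return float(np.min(np.abs(verts) @ c))
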