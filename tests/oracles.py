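"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's solver path: vertices of the flux
polytope {S v = 0, lb <= v <= ub} are enumerated as basic solutions and
objectives evaluated by exhaustion.  Only usable for tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9
) -> list[np.ndarray]:
    """All vertices (basic feasible solutions) of {S v = 0, lb <= v <= ub}."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-10)
    vertices: list[np.ndarray] = []
    n_nonbasic = n - r
    for nonbasic in itertools.combinations(range(n), n_nonbasic):
        basic = [j for j in range(n) if j not in nonbasic]
        S_b = S[:, basic]
        if np.linalg.matrix_rank(S_b, tol=1e-10) < r:
            continue
        for corner in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            if any(not np.isfinite(c) for c in corner):
                continue
            rhs = -S[:, nonbasic] @ np.array(corner)
            x_b, *_ = np.linalg.lstsq(S_b, rhs, rcond=None)
            if np.max(np.abs(S_b @ x_b - rhs)) > 1e-8:
                continue
            v = np.zeros(n)
            v[list(nonbasic)] = corner
            v[basic] = x_b
            if ((v >= lb - tol) & (v <= ub + tol)).all():
                if not any(np.allclose(v, w, atol=1e-8) for w in vertices):
                    vertices.append(v)
    return vertices


def lp_extreme(
    c: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray, sense: str = "max"
) -> float:
    """Exact LP optimum of c @ v by vertex enumeration."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        raise ValueError("no feasible vertex found")
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if sense == "max" else min(values)


def min_abs_sum(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, cols: list[int]
) -> float:
    """Exact minimum of sum_j |v_j| over the polytope, j in cols.

    Splits into orthants of the selected coordinates; within each orthant
    the objective is linear, so vertex enumeration is exact.
    """
    best = np.inf
    for signs in itertools.product((1.0, -1.0), repeat=len(cols)):
        lo, hi = lb.copy(), ub.copy()
        ok = True
        for j, s in zip(cols, signs):
            if s > 0:
                lo[j] = max(lo[j], 0.0)
            else:
                hi[j] = min(hi[j], 0.0)
            if lo[j] > hi[j] + 1e-12:
                ok = False
                break
        if not ok:
            continue
        c = np.zeros(S.shape[1])
        for j, s in zip(cols, signs):
            c[j] = s
        try:
            val = lp_extreme(c, S, lo, hi, sense="min")
        except ValueError:
            continue
        best = min(best, val)
    return best


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Hand implementation of the size-factor estimator for cross-checks."""
    counts = np.asarray(counts, dtype=float)
    keep = (counts > 0).all(axis=1)
    sub = counts[keep]
    geomean = np.exp(np.log(sub).mean(axis=1))
    return np.median(sub / geomean[:, None], axis=0)
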