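"""Cooperative trade-off flux balance analysis.

Three stages:

1. ``maximize_community_growth`` — LP maximum of the abundance-weighted
   community growth sum_i a_i mu_i.
2. ``cooperative_tradeoff`` — at trade-off fraction f, the unique
   member-growth vector minimizing sum_i mu_i^2 subject to retaining
   a_i-weighted community growth >= f * mu_star.  Solved exactly with
   Wolfe's minimum-norm-point algorithm over the projection of the flux
   polytope onto member-growth space, using LP oracles (the projection has
   at most as many dimensions as there are members, so the algorithm
   terminates in a handful of LP calls).
3. ``parsimonious_exchange_solution`` — with member growths pinned, the LP
   minimum of total absolute flux through environmental exchange reactions
   (split-variable formulation), yielding a parsimonious environmental
   footprint and, restricted to uptakes, the minimal medium.

Fluxes below the reporting tolerance tau are rounded to zero in returned
solutions only; the solver always works with unrounded values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .community import CommunityModel, Medium
from .errors import OptimizationError, ValidationError

__all__ = [
    "TradeoffResult",
    "FluxSolution",
    "maximize_community_growth",
    "cooperative_tradeoff",
    "parsimonious_exchange_solution",
    "minimal_medium",
    "flux_range",
    "FLUX_TOLERANCE",
]

FLUX_TOLERANCE = 1e-6  # tau: reported fluxes below this are rounded to 0
DEFAULT_GROWTH_DELTA = 1e-6  # relative tolerance when pinning member growths


@dataclass
class TradeoffResult:
    f: float
    mu_star: float
    member_growth: dict[str, float]
    status: str = "optimal"

    def community_growth(self, abundances: Mapping[str, float]) -> float:
        return sum(a * self.member_growth[m] for m, a in abundances.items())


@dataclass
class FluxSolution:
    fluxes: dict[str, float]  # tau-rounded, for reporting
    member_growth: dict[str, float]
    community_growth: float
    objective_value: float
    tolerance: float = FLUX_TOLERANCE
    status: str = "optimal"
    raw_fluxes: dict[str, float] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# LP plumbing

class _CommunityLP:
    """Cached matrices for repeated LP solves on one community model."""

    def __init__(self, cm: CommunityModel):
        self.cm = cm
        self.S, self.met_index, self.rxn_index, self.lb, self.ub = cm.to_matrices()
        self.rxn_ids = list(cm.reactions)
        self.n = len(self.rxn_ids)
        self.c_growth = cm.objective_vector()
        self.biomass_cols = {
            m: self.rxn_index[cm.biomass_reaction[m]] for m in cm.member_ids
        }
        self.env_cols = [
            self.rxn_index[r.id]
            for r in cm.reactions.values()
            if r.kind == "env_exchange"
        ]

    def solve(
        self,
        c: np.ndarray,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
        A_ub: sparse.spmatrix | None = None,
        b_ub: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float]:
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 2:
            raise OptimizationError(
                "LP infeasible: " + _diagnose_infeasible(self), status="infeasible"
            )
        if res.status == 3:
            raise OptimizationError("LP unbounded", status="unbounded")
        if res.status != 0:
            raise OptimizationError(f"LP solver failure: {res.message}")
        return res.x, float(res.fun)


def _diagnose_infeasible(lp: _CommunityLP) -> str:
    closed = [
        rid
        for rid in lp.rxn_ids
        if lp.cm.reactions[rid].kind == "env_exchange"
        and lp.cm.reactions[rid].lower_bound >= 0
    ]
    hints = ["check medium uptake caps and member growth pins"]
    if closed:
        hints.append(f"{len(closed)} environmental uptakes are closed")
    return "; ".join(hints)


def _round_fluxes(x: np.ndarray, tau: float) -> np.ndarray:
    out = x.copy()
    out[np.abs(out) < tau] = 0.0
    return out


def _solution_from_vector(
    lp: _CommunityLP, x: np.ndarray, objective_value: float, tau: float
) -> FluxSolution:
    member_growth = {
        m: float(x[col]) for m, col in lp.biomass_cols.items()
    }
    abundances = lp.cm.abundances
    community = sum(abundances[m] * mu for m, mu in member_growth.items())
    rounded = _round_fluxes(x[: lp.n], tau)
    return FluxSolution(
        fluxes={rid: float(v) for rid, v in zip(lp.rxn_ids, rounded)},
        member_growth=member_growth,
        community_growth=float(community),
        objective_value=objective_value,
        tolerance=tau,
        raw_fluxes={rid: float(v) for rid, v in zip(lp.rxn_ids, x[: lp.n])},
    )


# ---------------------------------------------------------------------------
# Stage 1

def maximize_community_growth(
    cm: CommunityModel, tau: float = FLUX_TOLERANCE
) -> tuple[float, FluxSolution]:
    """LP optimum of sum_i a_i mu_i subject to steady state and bounds."""
    lp = _CommunityLP(cm)
    x, fun = lp.solve(-lp.c_growth)
    mu_star = -fun
    if abs(mu_star) < 1e-12:
        mu_star = 0.0
    return mu_star, _solution_from_vector(lp, x, mu_star, tau)


# ---------------------------------------------------------------------------
# Stage 2: minimum-norm member-growth allocation (Wolfe's algorithm)

def _affine_minimizer(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-norm point in the affine hull of the columns of V.

    Returns (lambda, y) with sum(lambda) = 1 and y = V @ lambda.
    """
    k = V.shape[1]
    G = V.T @ V
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    b = np.zeros(k + 1)
    b[k] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    lam = sol[:k]
    return lam, V @ lam


def _min_norm_point(oracle, z0: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Wolfe's minimum-norm-point algorithm over a polytope given by a
    linear minimization oracle ``oracle(d) -> vertex`` (argmin d.z)."""
    V = [np.asarray(z0, dtype=float)]
    lam = np.array([1.0])
    x = V[0].copy()
    scale = max(1.0, float(x @ x))
    for _ in range(max_iter):
        q = oracle(x)
        scale = max(scale, float(q @ q))
        # Optimality: x is the MNP iff min_y <x, y> >= <x, x>.
        if float(x @ x) - float(x @ q) <= tol * scale:
            break
        if any(np.allclose(q, v, atol=1e-13, rtol=0.0) for v in V):
            break  # oracle cycling at numerical precision
        V.append(q)
        lam = np.append(lam, 0.0)
        while True:
            M = np.column_stack(V)
            mu, y = _affine_minimizer(M)
            if (mu >= -1e-13).all():
                lam, x = mu, y
                break
            # Step toward y until the first coordinate hits zero.
            diff = lam - mu
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(diff > 1e-15, lam / diff, np.inf)
            theta = min(1.0, float(ratios.min()))
            lam = (1 - theta) * lam + theta * mu
            lam[lam < 1e-12] = 0.0
            keep = lam > 0
            if keep.all():
                # Degenerate step dropped nothing; accept the clipped point
                # and let the outer oracle check certify or refute it.
                lam = lam / lam.sum()
                x = M @ lam
                break
            V = [v for v, k in zip(V, keep) if k]
            lam = lam[keep]
            lam = lam / lam.sum()
            x = np.column_stack(V) @ lam
    return x


def cooperative_tradeoff(
    cm: CommunityModel,
    f: float,
    weights: Mapping[str, float] | None = None,
) -> TradeoffResult:
    """Stage-2 allocation: minimize sum_i w_i mu_i^2 subject to retaining a
    fraction f of the community growth optimum.

    ``weights`` defaults to 1 for every member (the unweighted Euclidean
    shortest path from the zero-growth inoculation point); passing the
    member abundances gives the abundance-weighted variant.
    """
    if not 0.0 < f <= 1.0:
        raise ValidationError(f"trade-off fraction f must be in (0, 1], got {f}")
    lp = _CommunityLP(cm)
    member_ids = cm.member_ids
    k = len(member_ids)
    w = np.ones(k)
    if weights is not None:
        w = np.array([weights[m] for m in member_ids], dtype=float)
        if (w <= 0).any():
            raise ValidationError("stage-2 weights must be positive")
    sqrt_w = np.sqrt(w)
    cols = np.array([lp.biomass_cols[m] for m in member_ids])
    a = lp.c_growth[cols]  # abundances in member order

    mu_star, _ = maximize_community_growth(cm)
    if mu_star <= 0.0:
        return TradeoffResult(f, mu_star, {m: 0.0 for m in member_ids})

    # Trade-off constraint sum_i a_i mu_i >= f mu_star as A_ub x <= b_ub.
    row = sparse.csr_matrix(
        (-a, (np.zeros(k, dtype=int), cols)), shape=(1, lp.n)
    )
    b_ub = np.array([-f * mu_star])

    def oracle(z: np.ndarray) -> np.ndarray:
        # Minimize <z, sqrt(w) * mu> over the constrained flux polytope.
        c = np.zeros(lp.n)
        c[cols] = z * sqrt_w
        x, _ = lp.solve(c, A_ub=row, b_ub=b_ub)
        return x[cols] * sqrt_w

    z0 = oracle(np.zeros(k))
    z = _min_norm_point(oracle, z0)
    mu = z / sqrt_w
    mu = np.maximum(mu, 0.0)
    achieved = float(a @ mu)
    if achieved < f * mu_star - 1e-7:
        raise OptimizationError(
            f"trade-off stage failed to retain f*mu_star "
            f"({achieved} < {f * mu_star})"
        )
    return TradeoffResult(
        f=f,
        mu_star=mu_star,
        member_growth={m: float(v) for m, v in zip(member_ids, mu)},
    )


# ---------------------------------------------------------------------------
# Stage 3: parsimonious environmental exchange

def _pinned_bounds(
    lp: _CommunityLP, tr: TradeoffResult, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    lb = lp.lb.copy()
    ub = lp.ub.copy()
    for m, col in lp.biomass_cols.items():
        mu = tr.member_growth[m]
        slack = delta * max(abs(mu), 1.0)
        lb[col] = max(lb[col], mu - slack)
        ub[col] = min(ub[col], mu + slack)
    return lb, ub


def parsimonious_exchange_solution(
    cm: CommunityModel,
    tr: TradeoffResult,
    delta: float = DEFAULT_GROWTH_DELTA,
    tau: float = FLUX_TOLERANCE,
) -> FluxSolution:
    """Minimize total |flux| over environmental exchange reactions with each
    member growth pinned to its trade-off value (+/- delta, relative)."""
    lp = _CommunityLP(cm)
    lb, ub = _pinned_bounds(lp, tr, delta)
    n, n_env = lp.n, len(lp.env_cols)

    # Split variables: v_e = p_e - q_e with p, q >= 0; minimize sum(p + q).
    env = np.array(lp.env_cols)
    S_aug = sparse.hstack(
        [lp.S, sparse.csr_matrix((lp.S.shape[0], 2 * n_env))], format="csr"
    )
    link = sparse.lil_matrix((n_env, n + 2 * n_env))
    for i, col in enumerate(env):
        link[i, col] = 1.0
        link[i, n + i] = -1.0
        link[i, n + n_env + i] = 1.0
    A_eq = sparse.vstack([S_aug, link.tocsr()], format="csr")
    b_eq = np.zeros(A_eq.shape[0])
    c = np.zeros(n + 2 * n_env)
    c[n:] = 1.0
    lo = np.concatenate([lb, np.zeros(2 * n_env)])
    hi = np.concatenate([ub, np.full(2 * n_env, np.inf)])
    # The delta pins alone would let growth slip below the trade-off regime;
    # keep the community-growth constraint of the identified regime exact.
    growth_row = sparse.csr_matrix(
        (
            -lp.c_growth[list(lp.biomass_cols.values())],
            (
                np.zeros(len(lp.biomass_cols), dtype=int),
                list(lp.biomass_cols.values()),
            ),
        ),
        shape=(1, n + 2 * n_env),
    )
    b_growth = np.array([-tr.f * tr.mu_star]) if tr.mu_star > 0 else np.array([0.0])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=growth_row,
        b_ub=b_growth,
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    if res.status == 2:
        raise OptimizationError(
            "parsimonious exchange LP infeasible at the pinned growths; "
            f"try a larger delta (current {delta})",
            status="infeasible",
        )
    if res.status != 0:
        raise OptimizationError(f"parsimonious exchange LP failed: {res.message}")
    x = res.x[:n]
    total = float(np.abs(x[env]).sum())
    sol = _solution_from_vector(lp, x, total, tau)
    return sol


def minimal_medium(
    cm: CommunityModel,
    tr: TradeoffResult,
    delta: float = DEFAULT_GROWTH_DELTA,
    tau: float = FLUX_TOLERANCE,
) -> Medium:
    """Uptake vector of the parsimonious solution, as positive caps.

    Minimality is in total uptake flux (not component count): the caps are
    the uptakes of the exchange-flux-minimal solution at the trade-off
    growth regime.
    """
    sol = parsimonious_exchange_solution(cm, tr, delta=delta, tau=tau)
    uptake: dict[str, float] = {}
    for rxn in cm.reactions.values():
        if rxn.kind != "env_exchange":
            continue
        v = sol.fluxes[rxn.id]
        if v < -tau:
            base = rxn.lumen_metabolite.split("__", 1)[1]
            uptake[base] = -v
    return Medium(uptake)


def flux_range(
    cm: CommunityModel,
    reaction_id: str,
    tr: TradeoffResult,
    delta: float = DEFAULT_GROWTH_DELTA,
) -> tuple[float, float]:
    """Min and max flux of one reaction with member growths pinned."""
    lp = _CommunityLP(cm)
    if reaction_id not in lp.rxn_index:
        raise ValidationError(f"unknown reaction {reaction_id!r}")
    lb, ub = _pinned_bounds(lp, tr, delta)
    c = np.zeros(lp.n)
    c[lp.rxn_index[reaction_id]] = 1.0
    _, lo = lp.solve(c, lb=lb, ub=ub)
    _, hi = lp.solve(-c, lb=lb, ub=ub)
    return float(lo), float(-hi)


# ---------------------------------------------------------------------------
# Writers

def write_solution_tsv(
    sol: FluxSolution, cm: CommunityModel, path: str | Path
) -> None:
    """TSV of (reaction, member, metabolite, flux), export-positive."""
    import pandas as pd

    rows = []
    for rxn in cm.reactions.values():
        met = ""
        if rxn.lumen_metabolite is not None:
            met = rxn.lumen_metabolite.split("__", 1)[1]
        rows.append(
            {
                "reaction": rxn.id,
                "member": rxn.member or "environment",
                "metabolite": met,
                "flux": sol.fluxes[rxn.id],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(
    tr: TradeoffResult, sol: FluxSolution, path: str | Path
) -> None:
    payload = {
        "mu_star": tr.mu_star,
        "f": tr.f,
        "member_growth": tr.member_growth,
        "community_growth": sol.community_growth,
        "total_environmental_exchange": sol.objective_value,
        "status": sol.status,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
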