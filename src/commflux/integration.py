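"""Transcript-abundance integration into reaction bounds, and calibration.

Per-reaction expression scores are computed by evaluating each reaction's
gene-product rule on linear-scale transcript values (back-transformed from
the log2 table produced by :func:`commflux.expression.log_normalize`).
Scored reactions are down-weighted by w = beta * min(1, (E / E_ref)^alpha)
relative to a member-wise reference quantile E_ref, so under-expressed
reactions shrink toward zero capacity while well-expressed reactions keep
their base bounds.  The steepness parameter alpha is calibrated jointly
with the community trade-off fraction f against measured community growth
rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .community import MEMBER_SEP, CommunityModel
from .ctfba import cooperative_tradeoff
from .errors import ValidationError
from .gem_core import MetabolicModel, evaluate_gpr

__all__ = [
    "IntegrationParams",
    "CalibrationDataset",
    "CalibrationResult",
    "reaction_expression_scores",
    "expression_bounds",
    "integrate_community",
    "calibrate",
    "default_f_grid",
    "default_alpha_grid",
]

#: Near-tie tolerance on Pearson r during grid selection.  Predicted
#: community growth is exactly proportional to f (the trade-off constraint
#: binds whenever zero growth is feasible), so r alone cannot distinguish
#: trade-off fractions; near-ties are resolved by absolute agreement (RMSE)
#: with the measured rates before the parsimony tie-breaks.
R_TIE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class IntegrationParams:
    alpha: float = 1.0  # steepness of the under-expression penalty
    beta: float = 1.0  # cap scale (w <= beta)
    reference_quantile: float = 0.75
    pseudocount: float = 1.0  # matches the log-transform pseudocount

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        if not 0.0 < self.reference_quantile < 1.0:
            raise ValidationError("reference_quantile must be in (0, 1)")


def reaction_expression_scores(
    model: MetabolicModel,
    member_log_expr: Mapping[str, float],
    pseudocount: float = 1.0,
    missing_policy: str = "median",
) -> dict[str, float]:
    """Linear-scale expression score per reaction with a gene-product rule.

    Log2 values x are back-transformed to max(0, 2^x - pseudocount) before
    rule evaluation, keeping OR-sums additive in transcript abundance.
    Reactions without a rule are absent from the result.
    """
    linear = {
        g: max(0.0, float(2.0 ** x) - pseudocount)
        for g, x in member_log_expr.items()
    }
    scores: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        scores[rxn.id] = evaluate_gpr(rxn.gpr, linear, missing_policy=missing_policy)
    return scores


def _weight(score: float, e_ref: float, params: IntegrationParams) -> float:
    if score <= 0.0:
        return 0.0
    return params.beta * min(1.0, (score / e_ref) ** params.alpha)


def _reference(scores: Mapping[str, float], params: IntegrationParams) -> float:
    values = np.array(list(scores.values()), dtype=float)
    if values.size == 0 or (values <= 0).all():
        raise ValidationError(
            "cannot derive an expression reference: all reaction scores are zero"
        )
    e_ref = float(np.quantile(values, params.reference_quantile))
    if e_ref <= 0.0:
        # Quantile landed in the zero tail; fall back to the smallest
        # positive score so weights stay defined.
        e_ref = float(values[values > 0].min())
    return e_ref


def expression_bounds(
    model: MetabolicModel,
    scores: Mapping[str, float],
    params: IntegrationParams,
) -> MetabolicModel:
    """Scale scored reactions' bounds by w = beta * min(1, (E/E_ref)^alpha).

    Both bounds are multiplied by the (non-negative) weight, preserving
    reaction directionality; unscored reactions are untouched.
    """
    e_ref = _reference(scores, params)
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id not in scores:
            continue
        w = _weight(scores[rxn.id], e_ref, params)
        rxn.lower_bound *= w
        rxn.upper_bound *= w
    return out


def integrate_community(
    cm: CommunityModel,
    member_log_expr: Mapping[str, Mapping[str, float]],
    params: IntegrationParams,
) -> CommunityModel:
    """Apply expression bounds member-by-member inside a community model.

    Members without expression data are left untouched.
    """
    out = cm.copy()
    for spec in cm.members:
        mid = spec.model.id
        if mid not in member_log_expr:
            continue
        scores = reaction_expression_scores(
            spec.model, member_log_expr[mid], pseudocount=params.pseudocount
        )
        if not scores:
            continue
        e_ref = _reference(scores, params)
        for rxn_id, score in scores.items():
            prefixed = f"{mid}{MEMBER_SEP}{rxn_id}"
            if prefixed not in out.reactions:
                continue
            w = _weight(score, e_ref, params)
            rxn = out.reactions[prefixed]
            rxn.lower_bound *= w
            rxn.upper_bound *= w
    return out


# ---------------------------------------------------------------------------
# Calibration

@dataclass
class CalibrationDataset:
    community: CommunityModel  # medium already applied
    member_log_expr: dict[str, dict[str, float]]
    measured_growth: float
    label: str = ""


@dataclass
class CalibrationResult:
    grid: list[dict]  # records with f, alpha, r, rmse
    best: tuple[float, float]  # (f, alpha)
    pairs: list[tuple[float, float]]  # (predicted, measured) at best


def default_f_grid() -> list[float]:
    return [round(0.1 * k, 1) for k in range(1, 11)]


def default_alpha_grid() -> list[float]:
    # Log-spaced over [0.1, 10] and centred on 1.0.
    return [float(10.0 ** (k / 3.0)) for k in range(-3, 4)]


def calibrate(
    datasets: Sequence[CalibrationDataset],
    f_grid: Sequence[float] | None = None,
    alpha_grid: Sequence[float] | None = None,
    params: IntegrationParams = IntegrationParams(),
) -> CalibrationResult:
    """Grid-search (f, alpha) maximizing Pearson correlation between
    measured and predicted community growth rates.

    Near-ties in r are broken by smaller RMSE, then smaller alpha, then
    larger f (see :data:`R_TIE_TOLERANCE` for why RMSE participates).
    """
    datasets = list(datasets)
    if len(datasets) < 3:
        warnings.warn(
            f"Pearson correlation is degenerate with {len(datasets)} datasets",
            stacklevel=2,
        )
    f_grid = list(f_grid) if f_grid is not None else default_f_grid()
    alpha_grid = list(alpha_grid) if alpha_grid is not None else default_alpha_grid()
    if not f_grid or not alpha_grid:
        raise ValidationError("calibration grids must be non-empty")

    measured = np.array([d.measured_growth for d in datasets], dtype=float)
    records: list[dict] = []
    predictions: dict[tuple[float, float], np.ndarray] = {}
    for alpha in alpha_grid:
        p = IntegrationParams(
            alpha=alpha,
            beta=params.beta,
            reference_quantile=params.reference_quantile,
            pseudocount=params.pseudocount,
        )
        integrated = [
            integrate_community(d.community, d.member_log_expr, p) for d in datasets
        ]
        for f in f_grid:
            pred = np.array(
                [
                    cooperative_tradeoff(cm_i, f).community_growth(
                        cm_i.abundances
                    )
                    for cm_i in integrated
                ]
            )
            predictions[(f, alpha)] = pred
            rmse = float(np.sqrt(np.mean((pred - measured) ** 2)))
            if np.std(pred) < 1e-12 or np.std(measured) < 1e-12 or len(datasets) < 2:
                r = None
            else:
                r = float(np.corrcoef(pred, measured)[0, 1])
            records.append({"f": f, "alpha": alpha, "r": r, "rmse": rmse})

    scored = [rec for rec in records if rec["r"] is not None]
    if not scored:
        raise ValidationError(
            "Pearson r undefined at every grid point (constant predictions)"
        )
    r_max = max(rec["r"] for rec in scored)
    ties = [rec for rec in scored if rec["r"] >= r_max - R_TIE_TOLERANCE]
    best_rec = min(ties, key=lambda rec: (rec["rmse"], rec["alpha"], -rec["f"]))
    best = (best_rec["f"], best_rec["alpha"])
    pairs = [
        (float(p), float(m)) for p, m in zip(predictions[best], measured)
    ]
    return CalibrationResult(grid=records, best=best, pairs=pairs)


# ---------------------------------------------------------------------------
# Report writers

def write_calibration_tsv(result: CalibrationResult, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(result.grid).to_csv(path, sep="\t", index=False)


def write_chosen_params_json(result: CalibrationResult, path: str | Path) -> None:
    f, alpha = result.best
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"f": f, "alpha": alpha}, fh, indent=1)


def write_predicted_vs_measured_tsv(
    result: CalibrationResult, path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(result.pairs, columns=["predicted", "measured"]).to_csv(
        path, sep="\t", index=False
    )
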