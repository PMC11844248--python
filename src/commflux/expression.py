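"""Count normalization, per-member splitting, and growth-rate estimation.

Counts are split by community member before any normalization so that
taxonomic composition shifts do not masquerade as per-taxon transcriptional
changes.  Size factors use the median-of-ratios estimator; nFPK divides the
size-factor-normalized count by gene length in kilobases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "SizeFactors",
    "GrowthCurve",
    "GrowthRateFit",
    "split_counts_by_member",
    "size_factors",
    "nfpk",
    "log_normalize",
    "growth_rate_from_od",
    "absolute_abundance",
    "read_counts_tsv",
    "read_od_tsv",
]


@dataclass
class CountMatrix:
    """Gene x sample RNA fragment counts with gene metadata.

    ``counts`` is indexed by gene id with one column per sample; every gene
    must have a positive length (bp) and a member assignment.
    """

    counts: pd.DataFrame
    gene_lengths: dict[str, float]
    gene_member: dict[str, str]

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        for g in self.counts.index:
            if g not in self.gene_lengths or self.gene_lengths[g] <= 0:
                raise ValidationError(f"gene {g!r} lacks a positive length")
            if g not in self.gene_member:
                raise ValidationError(f"gene {g!r} lacks a member assignment")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SizeFactors:
    factors: dict[str, float]

    def __post_init__(self):
        for s, v in self.factors.items():
            if not v > 0:
                raise ValidationError(f"size factor for sample {s!r} must be > 0")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]


@dataclass
class GrowthCurve:
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # positive
    reactor: str = ""
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size < 2:
            raise ValidationError("growth curve needs at least 2 points")
        if not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if not (self.od > 0).all():
            raise ValidationError("OD values must be positive")


@dataclass
class GrowthRateFit:
    rate: float  # h^-1
    r_squared: float
    n_points: int
    window: tuple[float, float]


def split_counts_by_member(cm: CountMatrix) -> dict[str, CountMatrix]:
    """Partition genes by their member assignment (order-preserving)."""
    members: dict[str, list[str]] = {}
    for g in cm.genes:
        members.setdefault(cm.gene_member[g], []).append(g)
    return {
        member: CountMatrix(
            counts=cm.counts.loc[genes],
            gene_lengths={g: cm.gene_lengths[g] for g in genes},
            gene_member={g: member for g in genes},
        )
        for member, genes in members.items()
    }


def size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over genes g of c_gj / geomean_j'(c_gj'), where genes with
    any zero count are excluded from the median.
    """
    arr = cm.counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "size factors undefined: no gene with all-positive counts"
        )
    sub = arr[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    s = np.median(sub / geomean[:, None], axis=0)
    return SizeFactors({sample: float(v) for sample, v in zip(cm.samples, s)})


def nfpk(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    """Normalized fragments per kilobase: (c_gj / s_j) / (length_g / 1000)."""
    missing = [s for s in cm.samples if s not in sf.factors]
    if missing:
        raise ValidationError(f"size factors missing for samples {missing}")
    lengths = np.array([cm.gene_lengths[g] for g in cm.genes], dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    s = np.array([sf[j] for j in cm.samples], dtype=float)
    values = cm.counts.to_numpy(dtype=float) / s[None, :] / (lengths[:, None] / 1000.0)
    return pd.DataFrame(values, index=cm.genes, columns=cm.samples)


def fpk(cm: CountMatrix) -> pd.DataFrame:
    """Non-size-normalized fragments per kilobase (count / kb).

    Used for marker-gene activity, where MAG abundance and expression should
    both contribute to the signal.
    """
    lengths = np.array([cm.gene_lengths[g] for g in cm.genes], dtype=float)
    values = cm.counts.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    return pd.DataFrame(values, index=cm.genes, columns=cm.samples)


def log_normalize(
    cm: CountMatrix, sf: SizeFactors, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(c_gj / s_j + pseudocount)."""
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be positive")
    s = np.array([sf[j] for j in cm.samples], dtype=float)
    values = np.log2(cm.counts.to_numpy(dtype=float) / s[None, :] + pseudocount)
    return pd.DataFrame(values, index=cm.genes, columns=cm.samples)


def _fit_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y vs t and its R^2."""
    if np.ptp(y) == 0.0:
        return 0.0, 1.0
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    # A perfect 2-point fit has zero residual by construction.
    if len(t) == 2:
        r2 = 1.0
    return float(slope), r2


def growth_rate_from_od(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    min_r_squared: float = 0.98,
) -> GrowthRateFit:
    """Semi-logarithmic growth rate: least-squares slope of ln(OD) vs time.

    With no window given, the maximal contiguous window whose ln-linear fit
    reaches ``min_r_squared`` is used (falling back to the best window when
    none qualifies).
    """
    t_all = curve.times
    y_all = np.log(curve.od)
    if window is not None:
        mask = (t_all >= window[0]) & (t_all <= window[1])
        if mask.sum() < 2:
            raise ValidationError(
                f"window {window} selects {int(mask.sum())} points; need >= 2"
            )
        slope, r2 = _fit_window(t_all[mask], y_all[mask])
        return GrowthRateFit(slope, r2, int(mask.sum()), window)

    n = len(t_all)
    best: tuple[int, float, int, int] | None = None  # (length, r2, i, j)
    fallback: tuple[float, int, int] | None = None
    for i in range(n - 1):
        for j in range(i + 1, n):
            _, r2 = _fit_window(t_all[i : j + 1], y_all[i : j + 1])
            length = j - i + 1
            if r2 >= min_r_squared:
                key = (length, r2, -i)
                if best is None or key > (best[0], best[1], -best[2]):
                    best = (length, r2, i, j)
            if fallback is None or r2 > fallback[0]:
                fallback = (r2, i, j)
    if best is not None:
        i, j = best[2], best[3]
    else:
        i, j = fallback[1], fallback[2]
    slope, r2 = _fit_window(t_all[i : j + 1], y_all[i : j + 1])
    return GrowthRateFit(slope, r2, j - i + 1, (float(t_all[i]), float(t_all[j])))


def absolute_abundance(
    od: float, relative_abundances: Mapping[str, float]
) -> dict[str, float]:
    """Per-member absolute abundance estimate: OD x relative fraction."""
    total = 0.0
    for member, frac in relative_abundances.items():
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"fraction for {member!r} outside [0, 1]")
        total += frac
    if total > 1.0 + 1e-6:
        raise ValidationError(f"relative abundances sum to {total} > 1")
    return {member: od * frac for member, frac in relative_abundances.items()}


# ---------------------------------------------------------------------------
# TSV interfaces

def read_counts_tsv(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes x samples count table plus (gene, length_bp, member) metadata."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"gene", "length_bp", "member"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"gene metadata must have columns {sorted(required)}"
        )
    meta = meta.set_index("gene")
    return CountMatrix(
        counts=counts,
        gene_lengths=meta["length_bp"].astype(float).to_dict(),
        gene_member=meta["member"].astype(str).to_dict(),
    )


def write_counts_tsv(
    cm: CountMatrix, counts_path: str | Path, meta_path: str | Path
) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {
            "gene": cm.genes,
            "length_bp": [cm.gene_lengths[g] for g in cm.genes],
            "member": [cm.gene_member[g] for g in cm.genes],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_od_tsv(path: str | Path) -> list[GrowthCurve]:
    """Read an OD series TSV with columns time_h, od, reactor, condition."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "od", "reactor", "condition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"OD table must have columns {sorted(required)}")
    curves = []
    for (reactor, condition), grp in df.groupby(["reactor", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(float),
                od=grp["od"].to_numpy(float),
                reactor=str(reactor),
                condition=str(condition),
            )
        )
    return curves


def write_od_tsv(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append({"time_h": t, "od": od, "reactor": c.reactor, "condition": c.condition})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
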