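"""Exchange-flux tables and producer->consumer network extraction.

Exchange records are per gDW of the owning member, export-positive.  The
environment appears as a pseudo-member whose record closes each lumen
balance: sum over members of a_i * flux + environment flux = 0.

Cross-feeding edges carry community-weighted transfers: for each lumen
metabolite with at least one member exporter and one member importer, the
transferable amount min(total weighted export, total weighted import) is
allocated to (exporter, importer) pairs proportionally to each party's
share.  Pairwise attribution is a presentation convention; the underlying
solution constrains only the per-member net fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import LUMEN_PREFIX, CommunityModel
from .ctfba import FLUX_TOLERANCE, FluxSolution
from .errors import ValidationError

__all__ = [
    "ExchangeRecord",
    "CrossFeedingEdge",
    "exchange_table",
    "crossfeeding_network",
    "compare_conditions",
    "write_edge_tsv",
    "write_graphml",
]

ENVIRONMENT = "environment"


@dataclass(frozen=True)
class ExchangeRecord:
    member: str
    metabolite: str
    flux: float  # mmol / gDW_member / h, export-positive
    condition: str = ""


@dataclass(frozen=True)
class CrossFeedingEdge:
    producer: str
    consumer: str
    metabolite: str
    flux: float  # community-weighted transferred flux


def _base_name(lumen_met: str) -> str:
    return lumen_met[len(LUMEN_PREFIX):]


def exchange_table(
    sol: FluxSolution,
    cm: CommunityModel,
    condition: str = "",
    tau: float = FLUX_TOLERANCE,
) -> list[ExchangeRecord]:
    """One record per member<->lumen exchange with |flux| >= tau, plus
    environmental exchanges under the pseudo-member "environment"."""
    records: list[ExchangeRecord] = []
    for rxn in cm.reactions.values():
        if rxn.id not in sol.fluxes:
            raise ValidationError(
                f"solution does not cover reaction {rxn.id!r}; "
                "was it produced from this community model?"
            )
        v = sol.fluxes[rxn.id]
        if rxn.kind == "member_exchange":
            if abs(v) >= tau:
                records.append(
                    ExchangeRecord(
                        member=rxn.member,
                        metabolite=_base_name(rxn.lumen_metabolite),
                        flux=v,
                        condition=condition,
                    )
                )
        elif rxn.kind == "env_exchange":
            # Environment flux recorded so that weighted member fluxes plus
            # the environment record sum to zero per metabolite.
            if abs(v) >= tau:
                records.append(
                    ExchangeRecord(
                        member=ENVIRONMENT,
                        metabolite=_base_name(rxn.lumen_metabolite),
                        flux=-v,
                        condition=condition,
                    )
                )
    return records


def crossfeeding_network(
    sol: FluxSolution,
    cm: CommunityModel,
    tau: float = FLUX_TOLERANCE,
) -> list[CrossFeedingEdge]:
    """Producer->consumer edges per lumen metabolite, proportional allocation."""
    abundances = cm.abundances
    by_met: dict[str, list[tuple[str, float]]] = {}
    for rxn in cm.reactions.values():
        if rxn.kind != "member_exchange":
            continue
        v = sol.fluxes.get(rxn.id, 0.0)
        if abs(v) < tau:
            continue
        by_met.setdefault(_base_name(rxn.lumen_metabolite), []).append(
            (rxn.member, v)
        )

    edges: list[CrossFeedingEdge] = []
    for met, flows in by_met.items():
        exporters = [(m, abundances[m] * v) for m, v in flows if v > 0]
        importers = [(m, -abundances[m] * v) for m, v in flows if v < 0]
        if not exporters or not importers:
            continue
        total_export = sum(w for _, w in exporters)
        total_import = sum(w for _, w in importers)
        transferred = min(total_export, total_import)
        for producer, w_exp in exporters:
            for consumer, w_imp in importers:
                if producer == consumer:
                    continue
                flux = transferred * (w_exp / total_export) * (w_imp / total_import)
                if flux > tau:
                    edges.append(
                        CrossFeedingEdge(
                            producer=producer,
                            consumer=consumer,
                            metabolite=met,
                            flux=flux,
                        )
                    )
    return edges


def compare_conditions(
    tables: Mapping[str, Sequence[ExchangeRecord]],
) -> pd.DataFrame:
    """Align per-condition exchange records into mean +/- sd per
    (member, metabolite), with pairwise condition deltas of the means.

    ``tables`` maps condition label -> records pooled over replicates (one
    record per replicate per member per metabolite).
    """
    if not tables:
        raise ValidationError("no conditions to compare")
    frames = []
    for condition, records in tables.items():
        if not records:
            continue
        df = pd.DataFrame(
            [
                {"member": r.member, "metabolite": r.metabolite, "flux": r.flux}
                for r in records
            ]
        )
        agg = df.groupby(["member", "metabolite"])["flux"].agg(["mean", "std", "count"])
        agg["std"] = agg["std"].fillna(0.0)
        agg.columns = pd.MultiIndex.from_product([[condition], agg.columns])
        frames.append(agg)
    if not frames:
        raise ValidationError("all conditions are empty")

    member_sets = [set(f.index.get_level_values("member")) for f in frames]
    if len(member_sets) > 1 and set.intersection(*member_sets) == set():
        import warnings

        warnings.warn("conditions have disjoint member sets; outer join", stacklevel=2)
    out = pd.concat(frames, axis=1, join="outer")

    conditions = list(tables)
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1:]:
            if (c1, "mean") in out.columns and (c2, "mean") in out.columns:
                out[("delta", f"{c1}-{c2}")] = (
                    out[(c1, "mean")].fillna(0.0) - out[(c2, "mean")].fillna(0.0)
                )
    return out


def write_edge_tsv(edges: Sequence[CrossFeedingEdge], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "producer": e.producer,
                "metabolite": e.metabolite,
                "consumer": e.consumer,
                "flux": e.flux,
            }
            for e in edges
        ]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(edges: Sequence[CrossFeedingEdge], path: str | Path) -> None:
    import networkx as nx

    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(e.producer, e.consumer, metabolite=e.metabolite, flux=e.flux)
    nx.write_graphml(g, str(path))


def write_exchange_summary_tsv(
    records: Sequence[ExchangeRecord], path: str | Path
) -> None:
    """Flat per-member exchange table in the style of a stacked bar layout."""
    pd.DataFrame(
        [
            {
                "member": r.member,
                "metabolite": r.metabolite,
                "condition": r.condition,
                "flux": r.flux,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
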