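"""Pathway completeness scoring, marker-gene activity, and net ATP yields
of the reductive-glycine route by stoichiometric optimization.

The built-in acetate-oxidation network lumps the enzyme steps with textbook
cofactor stoichiometry: acetate kinase invests one ATP (acetate ->
acetyl-phosphate), the reversed formate--THF ligase recovers one ATP per
formyl-THF released as formate, the glycine cleavage system emits one CO2
and one methylene-THF per glycine, and reversed pyruvate synthase consumes
two reduced ferredoxins.  Redox carriers (ferredoxin, NAD(H), thioredoxin)
close through free sinks so the accounting isolates substrate-level
phosphorylation; chemiosmotic yield is out of scope.  The thioredoxin
requirement of glycine reductase makes its in-vivo direction uncertain;
here thioredoxin is a free sink and the caveat stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .errors import OptimizationError, ValidationError
from .expression import CountMatrix, fpk
from .gem_core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "PathwayDefinition",
    "CompletenessRow",
    "pathway_completeness",
    "marker_expression",
    "rg_atp_yield",
    "build_rg_network",
    "WL_DEFINITION",
    "RG_DEFINITION",
    "GRD_DEFINITION",
    "write_completeness_tsv",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered steps, each satisfiable by any of its alternative genes."""

    name: str
    steps: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self):
        if not self.steps:
            raise ValidationError(f"pathway {self.name!r} has no steps")
        for step, alternatives in self.steps:
            if not alternatives:
                raise ValidationError(
                    f"step {step!r} of pathway {self.name!r} has no alternatives"
                )


def _defn(name: str, steps: list[tuple[str, set[str]]]) -> PathwayDefinition:
    return PathwayDefinition(
        name=name, steps=tuple((s, frozenset(a)) for s, a in steps)
    )


WL_DEFINITION = _defn(
    "WL",
    [
        ("formate_dehydrogenase", {"fdh"}),
        ("formate_thf_ligase", {"fhs"}),
        ("methylene_thf_dehydrogenase", {"folD"}),
        ("methylene_thf_reductase", {"metF", "metV"}),
        ("codh_acs_alpha", {"acsA"}),
        ("codh_acs_beta", {"acsB"}),
        ("codh_acs_gamma", {"acsC"}),
        ("codh_acs_delta", {"acsD"}),
        ("codh_acs_epsilon", {"acsE"}),
        ("phosphotransacetylase", {"pta", "ACSS"}),
        ("acetate_kinase", {"ackA", "ACSS"}),
    ],
)

RG_DEFINITION = _defn(
    "RG",
    [
        ("acetate_activation", {"ackA", "ACSS"}),
        ("acetyl_transfer", {"pta", "ACSS"}),
        ("pyruvate_interconversion", {"por", "pdh", "pfl"}),
        ("serine_dehydratase", {"sda"}),
        ("serine_hydroxymethyltransferase", {"glyA", "SHMT"}),
        ("gcs_decarboxylase", {"gcvP", "gcvPA", "gcvPB"}),
        ("gcs_transfer", {"gcvH", "gcvT"}),
        ("lipoamide_dehydrogenase", {"dld", "lpdA"}),
        ("methylene_thf_dehydrogenase", {"folD"}),
        ("formate_thf_ligase", {"fhs"}),
    ],
)

GRD_DEFINITION = _defn(
    "GRD",
    [
        ("glycine_reductase_a", {"grdA"}),
        ("glycine_reductase_b", {"grdB"}),
        ("glycine_reductase_e", {"grdE"}),
    ],
)

BUILTIN_DEFINITIONS = [WL_DEFINITION, RG_DEFINITION, GRD_DEFINITION]


@dataclass(frozen=True)
class CompletenessRow:
    member: str
    pathway: str
    fraction: float
    complete: bool
    step_presence: tuple[tuple[str, bool], ...]


def pathway_completeness(
    annotations: Mapping[str, Iterable[str]],
    definitions: Sequence[PathwayDefinition] | None = None,
) -> list[CompletenessRow]:
    """Score each member against each pathway definition.

    A step is present iff any of its alternative genes is annotated; a
    pathway is complete iff every step is present.
    """
    definitions = list(definitions) if definitions is not None else BUILTIN_DEFINITIONS
    rows = []
    for member, genes in annotations.items():
        gene_set = set(genes)
        for defn in definitions:
            presence = tuple(
                (step, bool(gene_set & alternatives))
                for step, alternatives in defn.steps
            )
            n_present = sum(1 for _, p in presence if p)
            fraction = n_present / len(defn.steps)
            rows.append(
                CompletenessRow(
                    member=member,
                    pathway=defn.name,
                    fraction=fraction,
                    complete=fraction == 1.0,
                    step_presence=presence,
                )
            )
    return rows


def write_completeness_tsv(rows: Sequence[CompletenessRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "member": r.member,
                "pathway": r.pathway,
                "fraction": r.fraction,
                "complete": r.complete,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def marker_expression(
    cm: CountMatrix,
    annotations: Mapping[str, Mapping[str, Sequence[str]]],
    marker_gene: str,
    sample_condition: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-member marker activity as non-size-normalized FPK (count per kb).

    FPK deliberately keeps MAG abundance in the signal, so both taxon
    abundance and expression contribute.  ``annotations`` maps member ->
    {gene symbol -> list of gene ids in the count matrix}; gene ids of the
    marker are summed per member.  Columns are samples, or conditions
    (means over samples) when ``sample_condition`` is given.
    """
    table = fpk(cm)
    rows = {}
    for member, symbols in annotations.items():
        gene_ids = [g for g in symbols.get(marker_gene, []) if g in table.index]
        if gene_ids:
            rows[member] = table.loc[gene_ids].sum(axis=0)
    if not rows:
        warnings.warn(
            f"marker gene {marker_gene!r} not annotated in any member", stacklevel=2
        )
        return pd.DataFrame()
    out = pd.DataFrame(rows).T
    if sample_condition is not None:
        out = out.T.groupby(
            pd.Series(sample_condition).reindex(out.columns)
        ).mean().T
    return out


# ---------------------------------------------------------------------------
# RG-pathway net ATP yield

def _met(mid: str, compartment: str, formula: str | None = None) -> Metabolite:
    return Metabolite(id=mid, name=mid, compartment=compartment, formula=formula)


def build_rg_network(close: Iterable[str] = ()) -> MetabolicModel:
    """Acetate-oxidation network with the canonical and grd entry branches.

    ``close`` may contain "grd" (shut the glycine-reductase entry) and/or
    "canonical" (shut the pyruvate/phosphotransacetylase route).
    """
    close = set(close)
    unknown = close - {"grd", "canonical"}
    if unknown:
        raise ValidationError(f"unknown branch names {sorted(unknown)}")

    mets = [
        _met("ac_e", "e", "C2H4O2"),
        _met("for_e", "e", "CH2O2"),
        _met("co2_e", "e", "CO2"),
        _met("nh3_e", "e", "H3N"),
        _met("acp_c", "c"),
        _met("accoa_c", "c"),
        _met("pyr_c", "c"),
        _met("ser_c", "c"),
        _met("gly_c", "c"),
        _met("thf_c", "c"),
        _met("mlthf_c", "c"),
        _met("fthf_c", "c"),
        _met("atp_c", "c"),
        _met("adp_c", "c"),
        _met("pi_c", "c"),
        _met("fdred_c", "c"),
        _met("fdox_c", "c"),
        _met("nad_c", "c"),
        _met("nadh_c", "c"),
        _met("trxred_c", "c"),
        _met("trxox_c", "c"),
    ]

    def rxn(rid, stoich, lb=0.0, ub=1000.0):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)

    reactions = [
        rxn("EX_ac", {"ac_e": -1.0}, lb=-1000.0),
        rxn("EX_for", {"for_e": -1.0}),
        rxn("EX_co2", {"co2_e": -1.0}),
        rxn("EX_nh3", {"nh3_e": -1.0}, lb=-1000.0),
        # Acetate activation: one ATP invested.
        rxn("ack", {"ac_e": -1, "atp_c": -1, "acp_c": 1, "adp_c": 1}),
        # Canonical entry branch.
        rxn("pta", {"acp_c": -1, "accoa_c": 1, "pi_c": 1}),
        rxn(
            "por_r",
            {"accoa_c": -1, "co2_e": -1, "fdred_c": -2, "pyr_c": 1, "fdox_c": 2},
        ),
        rxn("sda_r", {"pyr_c": -1, "nh3_e": -1, "ser_c": 1}),
        rxn("shmt", {"ser_c": -1, "thf_c": -1, "gly_c": 1, "mlthf_c": 1}),
        # grd entry branch (reversed glycine reductase).
        rxn(
            "grd_r",
            {"acp_c": -1, "nh3_e": -1, "trxox_c": -1, "gly_c": 1, "pi_c": 1, "trxred_c": 1},
        ),
        # Glycine cleavage: one CO2 and one methylene-THF per glycine.
        rxn(
            "gcs",
            {"gly_c": -1, "thf_c": -1, "nad_c": -1, "mlthf_c": 1, "co2_e": 1, "nh3_e": 1, "nadh_c": 1},
        ),
        rxn("fold", {"mlthf_c": -1, "nad_c": -1, "fthf_c": 1, "nadh_c": 1}),
        # Reversed formate--THF ligase: one ATP recovered per formate released.
        rxn(
            "fhs_r",
            {"fthf_c": -1, "adp_c": -1, "pi_c": -1, "for_e": 1, "thf_c": 1, "atp_c": 1},
        ),
        # Free redox sinks (H2-evolution surrogates).
        rxn("fd_sink", {"fdred_c": -1, "fdox_c": 1}, lb=-1000.0),
        rxn("nadh_sink", {"nadh_c": -1, "nad_c": 1}, lb=-1000.0),
        rxn("trx_sink", {"trxred_c": -1, "trxox_c": 1}, lb=-1000.0),
        # Substrate-level ATP accounting drain (the objective).
        rxn("atp_drain", {"atp_c": -1, "adp_c": 1, "pi_c": 1}),
    ]
    model = MetabolicModel(
        id="rg_network",
        metabolites=mets,
        reactions=reactions,
        genes=[],
        objective_reaction_id="atp_drain",
    )
    rmap = model.reaction_map()
    for r in ("EX_ac", "EX_for", "EX_co2", "EX_nh3"):
        rmap[r].is_exchange = True
    if "grd" in close:
        rmap["grd_r"].upper_bound = 0.0
    if "canonical" in close:
        rmap["pta"].upper_bound = 0.0
        rmap["por_r"].upper_bound = 0.0
    return model


def fba_max(
    model: MetabolicModel,
    objective_id: str | None = None,
    fixed: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, dict[str, float]]:
    """Plain FBA maximum of one reaction's flux on a single-taxon model."""
    objective_id = objective_id or model.objective_reaction_id
    rxn_ids = [r.id for r in model.reactions]
    rxn_index = {rid: i for i, rid in enumerate(rxn_ids)}
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for r in model.reactions:
        j = rxn_index[r.id]
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for met, coef in r.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    if fixed:
        for rid, (lo, hi) in fixed.items():
            j = rxn_index[rid]
            lb[j], ub[j] = lo, hi
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_index), len(rxn_ids)))
    c = np.zeros(len(rxn_ids))
    c[rxn_index[objective_id]] = -1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        raise OptimizationError("FBA infeasible", status="infeasible")
    if res.status == 3:
        raise OptimizationError("FBA unbounded", status="unbounded")
    if res.status != 0:
        raise OptimizationError(f"FBA solver failure: {res.message}")
    return -float(res.fun), {rid: float(v) for rid, v in zip(rxn_ids, res.x)}


def rg_atp_yield(variant: str) -> float:
    """Net ATP per acetate oxidized through the selected branch.

    "canonical": glycine-reductase entry closed; "grd": pyruvate route
    closed.  Acetate uptake is fixed to 1 and the ATP drain maximized.
    """
    if variant == "canonical":
        model = build_rg_network(close={"grd"})
    elif variant == "grd":
        model = build_rg_network(close={"canonical"})
    else:
        raise ValidationError(f"unknown variant {variant!r}")
    try:
        yield_, _ = fba_max(model, "atp_drain", fixed={"EX_ac": (-1.0, -1.0)})
    except OptimizationError as exc:
        raise OptimizationError(
            f"RG network infeasible for variant {variant!r}: {exc}"
        ) from exc
    return yield_
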