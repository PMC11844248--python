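"""Abundance-weighted community model assembly.

Member models are namespaced with a ``memberId__`` prefix and coupled
through a shared lumen compartment.  Member fluxes are expressed per gram
dry weight of that member; each member<->lumen transfer deposits its flux
into the lumen scaled by the member's relative abundance, so lumen mass
balances read sum_i a_i * (member exchange) + environmental exchange = 0.
Environmental exchange reactions are unscaled and carry the community-level
medium bounds.  Sign convention everywhere: negative = uptake, positive =
release.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .gem_core import MetabolicModel, Reaction, is_exchange_reaction

__all__ = [
    "MemberSpec",
    "Medium",
    "CommunityReaction",
    "CommunityModel",
    "build_community",
    "apply_medium",
    "member_exchanges",
    "read_abundance_tsv",
]

logger = logging.getLogger(__name__)

MEMBER_SEP = "__"
LUMEN_PREFIX = "lumen" + MEMBER_SEP
ENV_PREFIX = "EX_"
DEFAULT_ABUNDANCE_THRESHOLD = 0.01


@dataclass
class MemberSpec:
    model: MetabolicModel
    abundance: float

    def __post_init__(self):
        if not 0.0 < self.abundance <= 1.0:
            raise ValidationError(
                f"abundance for {self.model.id!r} must be in (0, 1], "
                f"got {self.abundance}"
            )


@dataclass
class Medium:
    """Maximum community uptake flux per environmental metabolite (>= 0)."""

    uptake: dict[str, float]

    def __post_init__(self):
        for met, v in self.uptake.items():
            if v < 0:
                raise ValidationError(
                    f"medium uptake for {met!r} must be >= 0, got {v}"
                )


@dataclass
class CommunityReaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    kind: str  # "internal" | "member_exchange" | "env_exchange"
    member: str | None = None
    lumen_metabolite: str | None = None
    source_reaction: str | None = None  # id in the member model


def lumen_base_name(met_id: str) -> str:
    """Map a member external-metabolite id to its lumen base name."""
    return met_id[:-2] if met_id.endswith("_e") else met_id


@dataclass
class CommunityModel:
    members: list[MemberSpec]
    reactions: dict[str, CommunityReaction]
    metabolites: list[str]  # all balanced rows (member mets + lumen mets)
    lumen_metabolites: list[str]
    biomass_reaction: dict[str, str]  # member id -> prefixed biomass rxn id

    @property
    def abundances(self) -> dict[str, float]:
        return {m.model.id: m.abundance for m in self.members}

    @property
    def member_ids(self) -> list[str]:
        return [m.model.id for m in self.members]

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            members=list(self.members),
            reactions={
                rid: CommunityReaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    kind=r.kind,
                    member=r.member,
                    lumen_metabolite=r.lumen_metabolite,
                    source_reaction=r.source_reaction,
                )
                for rid, r in self.reactions.items()
            },
            metabolites=list(self.metabolites),
            lumen_metabolites=list(self.lumen_metabolites),
            biomass_reaction=dict(self.biomass_reaction),
        )

    def to_matrices(self):
        """Stoichiometric matrix S (mets x rxns, CSR) plus bound arrays and
        index maps, for LP construction."""
        rxn_ids = list(self.reactions)
        rxn_index = {rid: i for i, rid in enumerate(rxn_ids)}
        met_index = {mid: i for i, mid in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for rid, rxn in self.reactions.items():
            for met, coef in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(rxn_index[rid])
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), len(rxn_ids))
        )
        lb = np.array([self.reactions[rid].lower_bound for rid in rxn_ids])
        ub = np.array([self.reactions[rid].upper_bound for rid in rxn_ids])
        return S, met_index, rxn_index, lb, ub

    def objective_vector(self) -> np.ndarray:
        """Coefficients of the community objective sum_i a_i mu_i."""
        c = np.zeros(len(self.reactions))
        rxn_index = {rid: i for i, rid in enumerate(self.reactions)}
        for member in self.members:
            c[rxn_index[self.biomass_reaction[member.model.id]]] = member.abundance
        return c


def build_community(
    members: Iterable[MemberSpec],
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
) -> CommunityModel:
    """Assemble the abundance-weighted community model.

    Members below the inclusion threshold are dropped with a warning and the
    remaining abundances renormalized to sum to 1.
    """
    members = list(members)
    if not members:
        raise ValidationError("empty community")
    ids = [m.model.id for m in members]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate member ids: {ids}")

    kept = [m for m in members if m.abundance > abundance_threshold]
    dropped = [m.model.id for m in members if m.abundance <= abundance_threshold]
    if dropped:
        logger.warning(
            "dropping members below abundance threshold %g: %s",
            abundance_threshold,
            dropped,
        )
    if not kept:
        raise ValidationError(
            f"no member above abundance threshold {abundance_threshold}"
        )
    total = sum(m.abundance for m in kept)
    kept = [MemberSpec(m.model, m.abundance / total) for m in kept]

    reactions: dict[str, CommunityReaction] = {}
    metabolites: list[str] = []
    lumen: dict[str, None] = {}
    biomass: dict[str, str] = {}

    for spec in kept:
        model = spec.model
        mid = model.id
        a = spec.abundance
        for met in model.metabolites:
            metabolites.append(f"{mid}{MEMBER_SEP}{met.id}")
        for rxn in model.reactions:
            prefixed = f"{mid}{MEMBER_SEP}{rxn.id}"
            if rxn.is_exchange or is_exchange_reaction(rxn, model):
                met_id, coef = next(iter(rxn.stoichiometry.items()))
                base = lumen_base_name(met_id)
                lumen_met = f"{LUMEN_PREFIX}{base}"
                lumen.setdefault(lumen_met, None)
                # Export-positive transfer: one unit of member flux deposits
                # a_i units into the lumen.
                stoich = {
                    f"{mid}{MEMBER_SEP}{met_id}": coef,
                    lumen_met: -coef * a,
                }
                reactions[prefixed] = CommunityReaction(
                    id=prefixed,
                    stoichiometry=stoich,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    kind="member_exchange",
                    member=mid,
                    lumen_metabolite=lumen_met,
                    source_reaction=rxn.id,
                )
            else:
                stoich = {
                    f"{mid}{MEMBER_SEP}{met}": coef
                    for met, coef in rxn.stoichiometry.items()
                }
                reactions[prefixed] = CommunityReaction(
                    id=prefixed,
                    stoichiometry=stoich,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    kind="internal",
                    member=mid,
                    source_reaction=rxn.id,
                )
        biomass[mid] = f"{mid}{MEMBER_SEP}{model.objective_reaction_id}"

    # Environmental exchanges: closed for uptake until a medium is applied.
    for lumen_met in lumen:
        base = lumen_met[len(LUMEN_PREFIX):]
        env_id = f"{ENV_PREFIX}{base}"
        reactions[env_id] = CommunityReaction(
            id=env_id,
            stoichiometry={lumen_met: -1.0},
            lower_bound=0.0,
            upper_bound=math.inf,
            kind="env_exchange",
            lumen_metabolite=lumen_met,
        )

    return CommunityModel(
        members=kept,
        reactions=reactions,
        metabolites=metabolites + list(lumen),
        lumen_metabolites=list(lumen),
        biomass_reaction=biomass,
    )


def apply_medium(cm: CommunityModel, medium: Medium) -> CommunityModel:
    """Return a copy with environmental uptake bounds set from the medium.

    Listed metabolites get lower bound -(max uptake); all other environmental
    uptakes are closed; secretion stays unbounded.  Medium entries without a
    matching lumen metabolite are skipped with a warning.
    """
    out = cm.copy()
    env = {
        r.lumen_metabolite[len(LUMEN_PREFIX):]: r
        for r in out.reactions.values()
        if r.kind == "env_exchange"
    }
    for base in medium.uptake:
        if base not in env:
            logger.warning("medium metabolite %r not present in lumen; skipped", base)
    for base, rxn in env.items():
        cap = medium.uptake.get(base, 0.0)
        rxn.lower_bound = -cap
        rxn.upper_bound = math.inf
    return out


def member_exchanges(cm: CommunityModel, member_id: str) -> list[tuple[str, str]]:
    """(reaction id, lumen metabolite) pairs for one member's transfers."""
    if member_id not in cm.member_ids:
        raise ValidationError(f"unknown member {member_id!r}")
    return [
        (r.id, r.lumen_metabolite)
        for r in cm.reactions.values()
        if r.kind == "member_exchange" and r.member == member_id
    ]


def read_abundance_tsv(path) -> dict[str, dict[str, float]]:
    """Read (member, condition, fraction) rows into {condition: {member: frac}}."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"member", "condition", "fraction"}
    if not required.issubset(df.columns):
        raise ValidationError(f"abundance table must have columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["condition"]), {})[str(row["member"])] = float(
            row["fraction"]
        )
    return out
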