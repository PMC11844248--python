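"""Single-taxon genome-scale model structures and readers/writers.

Models are plain dataclasses with a JSON dialect and an SBML Level 3
(core + fbc) subset for interchange.  Identifiers are preserved verbatim by
both round trips.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError
from .gpr import GeneProductRule, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Finding",
    "load_model",
    "save_model",
    "validate_model",
    "evaluate_gpr",
    "is_exchange_reaction",
    "parse_formula",
]

EXCHANGE_PREFIX = "EX_"
EXTERNAL_COMPARTMENT = "e"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GeneProductRule | None = None
    is_exchange: bool = False
    name: str = ""

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    objective_reaction_id: str

    def metabolite_map(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction_id=self.objective_reaction_id,
        )


def is_exchange_reaction(rxn: Reaction, model: MetabolicModel) -> bool:
    """Deterministic exchange classification: EX_ prefix and a single
    metabolite located in the external compartment."""
    if len(rxn.stoichiometry) != 1:
        return False
    if not rxn.id.startswith(EXCHANGE_PREFIX):
        return False
    met_id = next(iter(rxn.stoichiometry))
    mets = model.metabolite_map()
    return met_id in mets and mets[met_id].compartment == EXTERNAL_COMPARTMENT


def evaluate_gpr(
    rule: GeneProductRule,
    gene_scores: Mapping[str, float],
    missing_policy: str = "median",
) -> float:
    """AND = min of child scores, OR = sum of child scores."""
    if rule is None:
        raise ValidationError("cannot evaluate an empty gene-product rule")
    return rule.evaluate(gene_scores, missing_policy=missing_policy)


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style chemical formula into element counts."""
    counts: dict[str, int] = {}
    consumed = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != consumed:
            raise FormatError(f"cannot parse formula {formula!r}")
        consumed = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if consumed != len(formula):
        raise FormatError(f"cannot parse formula {formula!r}")
    return counts


def validate_model(model: MetabolicModel) -> list[Finding]:
    """Collect invariant violations as findings; never raises.

    The report is empty iff all structural invariants hold and every
    non-exchange, non-objective reaction with full formula coverage is
    elementally balanced (the biomass pseudo-reaction is exempt).
    """
    findings: list[Finding] = []
    mets = {}
    for m in model.metabolites:
        if m.id in mets:
            findings.append(Finding("error", "duplicate-metabolite", m.id))
        mets[m.id] = m
        if not m.compartment:
            findings.append(
                Finding("error", "missing-compartment", f"metabolite {m.id}")
            )
    rxns = {}
    gene_set = set(model.genes)
    for r in model.reactions:
        if r.id in rxns:
            findings.append(Finding("error", "duplicate-reaction", r.id))
        rxns[r.id] = r
        if not r.stoichiometry:
            findings.append(
                Finding("error", "empty-stoichiometry", f"reaction {r.id}")
            )
        if r.lower_bound > r.upper_bound:
            findings.append(
                Finding(
                    "error",
                    "inverted-bounds",
                    f"reaction {r.id}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}",
                )
            )
        for met_id in r.stoichiometry:
            if met_id not in mets:
                findings.append(
                    Finding(
                        "error",
                        "unknown-metabolite",
                        f"reaction {r.id} references {met_id}",
                    )
                )
        if r.is_exchange and len(r.stoichiometry) != 1:
            findings.append(
                Finding(
                    "error",
                    "exchange-arity",
                    f"exchange reaction {r.id} touches "
                    f"{len(r.stoichiometry)} metabolites",
                )
            )
        if r.gpr is not None:
            for g in r.gpr.genes:
                if g not in gene_set:
                    findings.append(
                        Finding(
                            "error",
                            "unknown-gene",
                            f"reaction {r.id} rule references {g}",
                        )
                    )
    if model.objective_reaction_id not in rxns:
        findings.append(
            Finding(
                "error",
                "missing-objective",
                f"objective reaction {model.objective_reaction_id!r} not found",
            )
        )

    # Elemental balance where formulas permit it.
    for r in model.reactions:
        if r.is_exchange or r.id == model.objective_reaction_id:
            continue
        balance: dict[str, float] = {}
        covered = True
        for met_id, coef in r.stoichiometry.items():
            met = mets.get(met_id)
            if met is None or met.formula is None:
                covered = False
                break
            try:
                elements = parse_formula(met.formula)
            except FormatError:
                findings.append(
                    Finding("warning", "bad-formula", f"metabolite {met_id}")
                )
                covered = False
                break
            for el, n in elements.items():
                balance[el] = balance.get(el, 0.0) + coef * n
        if covered:
            off = {el: v for el, v in balance.items() if abs(v) > 1e-9}
            if off:
                findings.append(
                    Finding(
                        "error",
                        "element-imbalance",
                        f"reaction {r.id} unbalanced: {off}",
                    )
                )
    return findings


def assert_valid(model: MetabolicModel) -> None:
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise ValidationError(
            f"model {model.id!r} invalid: "
            + "; ".join(f"{f.code}: {f.message}" for f in errors)
        )


# ---------------------------------------------------------------------------
# JSON dialect

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective_reaction_id": model.objective_reaction_id,
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in data["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r["gpr"]) if r.get("gpr") else None,
                is_exchange=bool(r.get("is_exchange", False)),
            )
            for r in data["reactions"]
        ]
        model = MetabolicModel(
            id=data["id"],
            metabolites=metabolites,
            reactions=reactions,
            genes=list(data["genes"]),
            objective_reaction_id=data["objective_reaction_id"],
        )
    except KeyError as exc:
        raise FormatError(f"JSON model missing required field: {exc}") from exc
    return model


# ---------------------------------------------------------------------------
# SBML (Level 3 core + fbc v2 subset)

def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    gene_sanitized = {}
    for g in model.genes:
        gp = mplug.createGeneProduct()
        gid = "G_" + re.sub(r"[^A-Za-z0-9_]", "_", g)
        gene_sanitized[g] = gid
        gp.setId(gid)
        gp.setLabel(g)

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name)
        rxn.setReversible(r.lower_bound < 0)
        rxn.setFast(False)
        for met_id, coef in r.stoichiometry.items():
            if coef < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        for side, value in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            param = sbml_model.createParameter()
            param.setId(f"{r.id}_{side}")
            param.setValue(value)
            param.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(f"{r.id}_lb")
        rplug.setUpperFluxBound(f"{r.id}_ub")
        if r.gpr is not None:
            ga = rplug.createGeneProductAssociation()
            # Match gene products by label; never auto-create new ones.
            code = ga.setAssociation(r.gpr.to_string(), False, False)
            if code != 0:
                raise FormatError(
                    f"cannot encode gene rule for reaction {r.id!r} in SBML"
                )

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(model.objective_reaction_id)
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise FormatError(f"could not write SBML to {path}")


def _assoc_to_string(assoc, label_of: dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return label_of.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        op = "and"
    elif isinstance(assoc, libsbml.FbcOr):
        op = "or"
    else:
        raise FormatError(f"unsupported association node {type(assoc).__name__}")
    parts = [
        _assoc_to_string(assoc.getAssociation(i), label_of)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + f" {op} ".join(parts) + ")"


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"no <model> element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if not sp.isSetCompartment() or not sp.getCompartment():
            raise FormatError(
                f"species {sp.getId()!r} has no compartment (line {sp.getLine()})"
            )
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    genes = []
    label_of = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            genes.append(label)
            label_of[gp.getId()] = label

    param_values = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        gpr = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_values.get(rplug.getLowerFluxBound(), -math.inf)
            if rplug.isSetUpperFluxBound():
                ub = param_values.get(rplug.getUpperFluxBound(), math.inf)
            ga = rplug.getGeneProductAssociation()
            if ga is not None and ga.getAssociation() is not None:
                gpr = parse_gpr(_assoc_to_string(ga.getAssociation(), label_of))
        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    objective_id = ""
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ValidationError(f"SBML model in {path} declares no active objective")

    model = MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction_id=objective_id,
    )
    for r in model.reactions:
        r.is_exchange = is_exchange_reaction(r, model)
    return model


# ---------------------------------------------------------------------------
# Public I/O

def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from JSON or SBML; the format defaults to the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"JSON parse error in {path} at line {exc.lineno}: {exc.msg}"
            ) from exc
        model = _model_from_dict(data)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    assert_valid(model)
    for r in model.reactions:
        r.is_exchange = is_exchange_reaction(r, model)
    return model


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model so that ``load_model`` reproduces it field for field."""
    path = Path(path)
    assert_valid(model)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, ensure_ascii=False)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")
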