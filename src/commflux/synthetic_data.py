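"""Synthetic inputs with known ground truth.

Three lumped-member archetypes mirror the roles in the cross-feeding
cascade of interest: a dominant hydrogenotrophic methanogen that overflows
aspartate and can burn formate; an acetate-oxidizing bacterium whose lumped
reversible pathway converts acetate to formate and hydrogen with a one-ATP
swing; and an amino-acid fermenter that degrades aspartate to acetate, CO2,
NH3 and H2 through fumarate/succinate intermediates.  Coefficients are
chosen so the worked LP examples have rational solutions and every model is
elementally consistent (ATP/ADP/Pi use the abstract element symbols X and P
so energy coupling balances too).

Feeding scenarios share a fixed carbon-mole total across the three main
labels, with H2 fed at four times the CO2 cap.  Ammonia and water are
always available as non-carbon supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunityModel, Medium, MemberSpec, apply_medium, build_community
from .ctfba import cooperative_tradeoff
from .errors import ValidationError
from .expression import CountMatrix, GrowthCurve, growth_rate_from_od, log_normalize, size_factors, split_counts_by_member
from .gem_core import MetabolicModel, Metabolite, Reaction, is_exchange_reaction
from .gpr import parse_gpr
from .integration import CalibrationDataset, IntegrationParams, integrate_community

__all__ = [
    "Scenario",
    "BenchmarkManifest",
    "Benchmark",
    "make_toy_member",
    "make_scenario",
    "simulate_counts",
    "simulate_od",
    "make_benchmark",
    "SCENARIO_LABELS",
    "MAIN_SCENARIOS",
]

SCENARIO_LABELS = ("Ac90/CO2_10", "Ac50/CO2_50", "CO2_100", "formate_only")
MAIN_SCENARIOS = SCENARIO_LABELS[:3]

#: Non-carbon support metabolites present in every scenario medium.
SUPPORT_UPTAKE = {"nh3": 10.0, "h2o": 1000.0}

TRUE_F = 0.5
TRUE_ALPHA = 1.0
DEFAULT_ABUNDANCES = {"methanogen": 0.85, "rg_bacterium": 0.09, "aa_fermenter": 0.06}


# ---------------------------------------------------------------------------
# Toy member models

_FORMULAS = {
    "h2_e": "H2",
    "co2_e": "CO2",
    "ch4_e": "CH4",
    "for_e": "CH2O2",
    "ac_e": "C2H4O2",
    "asp_e": "C4H7NO4",
    "nh3_e": "H3N",
    "h2o_e": "H2O",
    "fum_c": "C4H4O4",
    "succ_c": "C4H6O4",
    "atp_c": "XP",
    "adp_c": "X",
    "pi_c": "P",
}


def _mets(ids: Sequence[str]) -> list[Metabolite]:
    return [
        Metabolite(
            id=mid,
            name=mid.rsplit("_", 1)[0],
            compartment=mid.rsplit("_", 1)[1],
            formula=_FORMULAS.get(mid),
        )
        for mid in ids
    ]


def _exchange(met_id: str) -> Reaction:
    base = met_id.rsplit("_", 1)[0]
    return Reaction(
        id=f"EX_{base}",
        stoichiometry={met_id: -1.0},
        lower_bound=-1000.0,
        upper_bound=1000.0,
        is_exchange=True,
    )


def _rxn(rid, stoich, lb=0.0, ub=1000.0, gpr=None):
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr) if gpr else None,
    )


def make_toy_member(archetype: str) -> MetabolicModel:
    """Small elementally consistent member model for one archetype."""
    if archetype == "methanogen":
        mets = _mets(
            ["h2_e", "co2_e", "ch4_e", "for_e", "asp_e", "nh3_e", "h2o_e",
             "atp_c", "adp_c", "pi_c"]
        )
        reactions = [
            _exchange("h2_e"),
            _exchange("co2_e"),
            _exchange("ch4_e"),
            _exchange("for_e"),
            _exchange("asp_e"),
            _exchange("nh3_e"),
            _exchange("h2o_e"),
            _rxn(
                "mcr",
                {"h2_e": -4, "co2_e": -1, "adp_c": -1, "pi_c": -1,
                 "ch4_e": 1, "h2o_e": 2, "atp_c": 1},
                ub=6.0,
                gpr="mcrA and mcrB",
            ),
            _rxn(
                "fdh",
                {"for_e": -1, "co2_e": 1, "h2_e": 1},
                ub=20.0,
                gpr="fdhA",
            ),
            _rxn(
                "asp_syn",
                {"co2_e": -4, "nh3_e": -1, "h2_e": -6, "atp_c": -2,
                 "asp_e": 1, "h2o_e": 4, "adp_c": 2, "pi_c": 2},
                ub=10.0,
                gpr="aspS",
            ),
            # Growth consumes CO2, H2 and ATP, with forced aspartate overflow.
            _rxn(
                "biomass",
                {"co2_e": -2, "h2_e": -4, "atp_c": -10,
                 "asp_e": 0.1, "adp_c": 10, "pi_c": 10},
                ub=10.0,
            ),
        ]
        genes = ["mcrA", "mcrB", "fdhA", "aspS"]
    elif archetype == "rg_bacterium":
        mets = _mets(
            ["ac_e", "for_e", "h2_e", "co2_e", "h2o_e", "atp_c", "adp_c", "pi_c"]
        )
        reactions = [
            _exchange("ac_e"),
            _exchange("for_e"),
            _exchange("h2_e"),
            _exchange("co2_e"),
            _exchange("h2o_e"),
            # Lumped reversible acetate <-> 2 formate + 2 H2 with a 1-ATP swing.
            _rxn(
                "rg",
                {"ac_e": -1, "h2o_e": -2, "adp_c": -1, "pi_c": -1,
                 "for_e": 2, "h2_e": 2, "atp_c": 1},
                lb=-20.0,
                ub=20.0,
                gpr="ackA and fhs and folD",
            ),
            _rxn(
                "fdh_L",
                {"for_e": -1, "co2_e": 1, "h2_e": 1},
                ub=10.0,
                gpr="fdhL",
            ),
            _rxn(
                "biomass",
                {"ac_e": -1, "atp_c": -2, "adp_c": 2, "pi_c": 2},
                ub=10.0,
            ),
        ]
        genes = ["ackA", "fhs", "folD", "fdhL"]
    elif archetype == "aa_fermenter":
        mets = _mets(
            ["asp_e", "ac_e", "co2_e", "nh3_e", "h2_e", "h2o_e",
             "fum_c", "succ_c", "atp_c", "adp_c", "pi_c"]
        )
        reactions = [
            _exchange("asp_e"),
            _exchange("ac_e"),
            _exchange("co2_e"),
            _exchange("nh3_e"),
            _exchange("h2_e"),
            _exchange("h2o_e"),
            _rxn("asp_deam", {"asp_e": -1, "fum_c": 1, "nh3_e": 1}, ub=20.0,
                 gpr="aspA"),
            _rxn("frd", {"fum_c": -1, "h2_e": -1, "succ_c": 1}, ub=20.0,
                 gpr="frdA and frdB"),
            _rxn(
                "succ_ox",
                {"succ_c": -1, "h2o_e": -2, "adp_c": -1, "pi_c": -1,
                 "ac_e": 1, "co2_e": 2, "h2_e": 3, "atp_c": 1},
                ub=20.0,
                gpr="aarC or acl",
            ),
            _rxn(
                "biomass",
                {"asp_e": -0.5, "atp_c": -2, "adp_c": 2, "pi_c": 2},
                ub=10.0,
            ),
        ]
        genes = ["aspA", "frdA", "frdB", "aarC", "acl"]
    else:
        raise ValidationError(f"unknown archetype {archetype!r}")

    model = MetabolicModel(
        id=archetype,
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        objective_reaction_id="biomass",
    )
    for r in model.reactions:
        r.is_exchange = is_exchange_reaction(r, model)
    return model


# ---------------------------------------------------------------------------
# Feeding scenarios

@dataclass(frozen=True)
class Scenario:
    label: str
    c_tot: float
    medium: Medium

    @property
    def carbon_moles(self) -> float:
        up = self.medium.uptake
        return 2.0 * up.get("acetate", 0.0) + up.get("co2", 0.0) + up.get("formate", 0.0)


_SCENARIO_FRACTIONS = {
    "Ac90/CO2_10": (0.9, 0.1),
    "Ac50/CO2_50": (0.5, 0.5),
    "CO2_100": (0.0, 1.0),
}


def make_scenario(label: str, c_tot: float = 10.0) -> Scenario:
    """Uptake caps from the carbon split: acetate carries two carbons, and
    H2 is capped at four times the CO2 cap."""
    if c_tot <= 0:
        raise ValidationError("c_tot must be positive")
    uptake = dict(SUPPORT_UPTAKE)
    if label in _SCENARIO_FRACTIONS:
        frac_ac, frac_co2 = _SCENARIO_FRACTIONS[label]
        uptake["acetate"] = frac_ac * c_tot / 2.0
        uptake["co2"] = frac_co2 * c_tot
        uptake["h2"] = 4.0 * uptake["co2"]
        uptake["formate"] = 0.0
    elif label == "formate_only":
        uptake["acetate"] = 0.0
        uptake["co2"] = 0.0
        uptake["h2"] = 0.0
        uptake["formate"] = c_tot
    else:
        raise ValidationError(f"unknown scenario label {label!r}")
    return Scenario(label=label, c_tot=c_tot, medium=Medium(uptake))


# Lumen base names used by the toy models differ from the scenario's
# friendly names; map them when applying a scenario medium.
_MEDIUM_ALIASES = {"acetate": "ac", "formate": "for"}


def scenario_medium_for_community(scenario: Scenario) -> Medium:
    uptake = {}
    for met, cap in scenario.medium.uptake.items():
        uptake[_MEDIUM_ALIASES.get(met, met)] = cap
    return Medium(uptake)


# ---------------------------------------------------------------------------
# Count and OD simulation

def simulate_counts(
    base_means: Mapping[str, float],
    sample_size_factors: Mapping[str, float],
    sample_condition: Mapping[str, str],
    fold_changes: Mapping[str, Mapping[str, float]],
    dispersion: float,
    seed: int,
    gene_lengths: Mapping[str, float],
    gene_member: Mapping[str, str],
) -> CountMatrix:
    """Negative-binomial counts with mean s_j * q_g * FC_g(condition_j).

    ``fold_changes`` maps gene -> {condition: fold change} (default 1).
    ``dispersion`` is the NB dispersion phi (variance m + phi m^2); phi = 0
    gives Poisson counts.  Fully reproducible from the seed.
    """
    for name, vals in (("base means", base_means), ("size factors", sample_size_factors)):
        for k, v in vals.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive ({k!r} = {v})")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(base_means)
    samples = list(sample_size_factors)
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            cond = sample_condition[s]
            fc = fold_changes.get(g, {}).get(cond, 1.0)
            mean = base_means[g] * sample_size_factors[s] * fc
            if dispersion == 0.0:
                counts[i, j] = rng.poisson(mean)
            else:
                n = 1.0 / dispersion
                p = n / (n + mean)
                counts[i, j] = rng.negative_binomial(n, p)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=dict(gene_lengths),
        gene_member=dict(gene_member),
    )


def simulate_od(
    mu: float,
    od0: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    reactor: str = "",
    condition: str = "",
) -> GrowthCurve:
    """Exponential OD curve od0 * exp(mu t) with multiplicative log-normal noise."""
    if mu < 0:
        raise ValidationError("mu must be >= 0")
    if od0 <= 0:
        raise ValidationError("od0 must be positive")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0
    od = od0 * np.exp(mu * times) * np.exp(eps)
    return GrowthCurve(times=times, od=od, reactor=reactor, condition=condition)


# ---------------------------------------------------------------------------
# Benchmark

_BASE_MEANS = {
    # methanogen
    "mcrA": 2000.0, "mcrB": 1800.0, "fdhA": 1500.0, "aspS": 800.0,
    "mbg1": 1000.0, "mbg2": 600.0, "mbg3": 1200.0,
    # rg_bacterium
    "ackA": 1000.0, "fhs": 1200.0, "folD": 1500.0, "fdhL": 2500.0,
    "lbg1": 500.0, "lbg2": 800.0,
    # aa_fermenter
    "aspA": 900.0, "frdA": 700.0, "frdB": 800.0, "aarC": 400.0, "acl": 500.0,
    "sbg1": 600.0,
}

_GENE_MEMBER = {
    **{g: "methanogen" for g in ("mcrA", "mcrB", "fdhA", "aspS", "mbg1", "mbg2", "mbg3")},
    **{g: "rg_bacterium" for g in ("ackA", "fhs", "folD", "fdhL", "lbg1", "lbg2")},
    **{g: "aa_fermenter" for g in ("aspA", "frdA", "frdB", "aarC", "acl", "sbg1")},
}

# Condition-specific regulation: methanogenesis capacity drops and formate
# usage rises under acetate-rich feeding; the acetate-oxidation genes and
# the fermentation chain are under-expressed when CO2 is the only carbon
# source.
_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "mcrA": {"Ac90/CO2_10": 0.5, "Ac50/CO2_50": 0.8},
    "mcrB": {"Ac90/CO2_10": 0.5, "Ac50/CO2_50": 0.8},
    "fdhA": {"Ac90/CO2_10": 2.0, "Ac50/CO2_50": 1.5},
    "ackA": {"CO2_100": 0.15},
    "fhs": {"CO2_100": 0.15},
    "folD": {"CO2_100": 0.15},
    "frdA": {"CO2_100": 0.2},
    "frdB": {"CO2_100": 0.2},
}


@dataclass
class BenchmarkManifest:
    seed: int
    f_star: float
    alpha_star: float
    noise_sd: float
    abundances: dict[str, float]
    scenario_caps: dict[str, dict[str, float]]
    base_means: dict[str, float]
    fold_changes: dict[str, dict[str, float]]
    size_factors: dict[str, float]
    dispersion: float
    measured_growth: dict[str, float]
    true_growth: dict[str, float]
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


@dataclass
class Benchmark:
    members: dict[str, MetabolicModel]
    abundances: dict[str, float]
    scenarios: dict[str, Scenario]
    communities: dict[str, CommunityModel]  # per scenario, medium applied
    counts: CountMatrix
    datasets: list[CalibrationDataset]
    growth_curves: list[GrowthCurve]
    manifest: BenchmarkManifest


def _member_log_expr(counts: CountMatrix, sample: str) -> dict[str, dict[str, float]]:
    """Per-member log2 expression for one sample, normalized member-wise."""
    out: dict[str, dict[str, float]] = {}
    for member, sub in split_counts_by_member(counts).items():
        sf = size_factors(sub)
        table = log_normalize(sub, sf)
        out[member] = table[sample].to_dict()
    return out


def make_benchmark(
    seed: int,
    n_replicates: int = 3,
    c_tot: float = 10.0,
    noise_sd: float = 0.05,
    dispersion: float = 0.05,
    out_dir: str | Path | None = None,
) -> Benchmark:
    """Three-member community, three feeding scenarios, ``n_replicates``
    replicate datasets each, with measured growth generated by the pipeline
    itself at (f*, alpha*) plus seeded multiplicative noise.

    The returned datasets feed :func:`commflux.integration.calibrate`; the
    manifest records every generating parameter.
    """
    rng = np.random.default_rng(seed)
    members = {
        name: make_toy_member(name) for name in DEFAULT_ABUNDANCES
    }
    specs = [MemberSpec(members[m], a) for m, a in DEFAULT_ABUNDANCES.items()]
    base_cm = build_community(specs)

    scenarios = {label: make_scenario(label, c_tot) for label in MAIN_SCENARIOS}
    communities = {
        label: apply_medium(base_cm, scenario_medium_for_community(sc))
        for label, sc in scenarios.items()
    }

    samples = [
        f"{label}_r{k + 1}" for label in MAIN_SCENARIOS for k in range(n_replicates)
    ]
    sample_condition = {s: s.rsplit("_r", 1)[0] for s in samples}
    sample_sf = {
        s: float(np.exp(rng.normal(0.0, 0.3))) for s in samples
    }
    gene_lengths = {
        g: float(rng.integers(300, 3000)) for g in _BASE_MEANS
    }
    counts = simulate_counts(
        base_means=_BASE_MEANS,
        sample_size_factors=sample_sf,
        sample_condition=sample_condition,
        fold_changes=_FOLD_CHANGES,
        dispersion=dispersion,
        seed=int(rng.integers(0, 2**31)),
        gene_lengths=gene_lengths,
        gene_member=_GENE_MEMBER,
    )

    params_star = IntegrationParams(alpha=TRUE_ALPHA)
    datasets: list[CalibrationDataset] = []
    curves: list[GrowthCurve] = []
    measured: dict[str, float] = {}
    true_growth: dict[str, float] = {}
    od_times = np.linspace(0.0, 48.0, 7)
    for sample in samples:
        label = sample_condition[sample]
        expr = _member_log_expr(counts, sample)
        integrated = integrate_community(communities[label], expr, params_star)
        tr = cooperative_tradeoff(integrated, TRUE_F)
        growth = tr.community_growth(integrated.abundances)
        noisy = max(growth * (1.0 + noise_sd * float(rng.normal())), 0.01 * growth)
        curve = simulate_od(
            noisy, od0=0.05, times=od_times, noise_sd=0.0,
            seed=0, reactor=sample, condition=label,
        )
        fit = growth_rate_from_od(curve)
        curves.append(curve)
        true_growth[sample] = float(growth)
        measured[sample] = float(fit.rate)
        datasets.append(
            CalibrationDataset(
                community=communities[label],
                member_log_expr=expr,
                measured_growth=float(fit.rate),
                label=sample,
            )
        )

    manifest = BenchmarkManifest(
        seed=seed,
        f_star=TRUE_F,
        alpha_star=TRUE_ALPHA,
        noise_sd=noise_sd,
        abundances=dict(DEFAULT_ABUNDANCES),
        scenario_caps={
            label: dict(sc.medium.uptake) for label, sc in scenarios.items()
        },
        base_means=dict(_BASE_MEANS),
        fold_changes={g: dict(fc) for g, fc in _FOLD_CHANGES.items()},
        size_factors=sample_sf,
        dispersion=dispersion,
        measured_growth=measured,
        true_growth=true_growth,
    )
    bench = Benchmark(
        members=members,
        abundances=dict(DEFAULT_ABUNDANCES),
        scenarios=scenarios,
        communities=communities,
        counts=counts,
        datasets=datasets,
        growth_curves=curves,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _write_benchmark(bench: Benchmark, out_dir: Path) -> None:
    from .expression import write_counts_tsv, write_od_tsv
    from .gem_core import save_model

    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, model in bench.members.items():
        path = out_dir / f"{name}.json"
        save_model(model, path, format="json")
        files.append(path.name)
    write_counts_tsv(bench.counts, out_dir / "counts.tsv", out_dir / "genes.tsv")
    files += ["counts.tsv", "genes.tsv"]
    write_od_tsv(bench.growth_curves, out_dir / "od.tsv")
    files.append("od.tsv")
    abundance_rows = [
        {"member": m, "condition": label, "fraction": a}
        for label in bench.scenarios
        for m, a in bench.abundances.items()
    ]
    pd.DataFrame(abundance_rows).to_csv(
        out_dir / "abundances.tsv", sep="\t", index=False
    )
    files.append("abundances.tsv")
    scenarios_payload = {
        label: {"c_tot": sc.c_tot, "medium": sc.medium.uptake}
        for label, sc in bench.scenarios.items()
    }
    (out_dir / "scenarios.json").write_text(json.dumps(scenarios_payload, indent=1))
    files.append("scenarios.json")
    bench.manifest.files = files
    (out_dir / "manifest.json").write_text(bench.manifest.to_json())
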