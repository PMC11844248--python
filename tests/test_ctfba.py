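import numpy as np
import pytest

from commflux.community import Medium, MemberSpec, apply_medium, build_community
from commflux.ctfba import (
    FLUX_TOLERANCE,
    cooperative_tradeoff,
    flux_range,
    maximize_community_growth,
    minimal_medium,
    parsimonious_exchange_solution,
    write_solution_tsv,
    write_summary_json,
)
from commflux.errors import OptimizationError, ValidationError
from commflux.gem_core import MetabolicModel, Metabolite, Reaction
from commflux.pathways import fba_max

from conftest import substrate_member
from oracles import lp_extreme, min_abs_sum


class TestStage1:
    def test_symmetric_toy(self, symmetric_community):
        mu, sol = maximize_community_growth(symmetric_community)
        assert mu == pytest.approx(10.0, abs=1e-9)
        assert sol.community_growth == pytest.approx(10.0, abs=1e-9)

    def test_asymmetric_toy(self, asymmetric_community):
        mu, _ = maximize_community_growth(asymmetric_community)
        assert mu == pytest.approx(6.0, abs=1e-9)

    def test_closed_uptakes_zero_growth(self, symmetric_community):
        cm = apply_medium(symmetric_community, Medium({}))
        mu, _ = maximize_community_growth(cm)
        assert mu == 0.0

    def test_infeasible_reports_diagnostic(self):
        member = substrate_member("A")
        member.reaction_map()["growth"].lower_bound = 1.0  # forced growth
        cm = apply_medium(
            build_community([MemberSpec(member, 1.0)]), Medium({})
        )
        with pytest.raises(OptimizationError, match="infeasible|uptake"):
            maximize_community_growth(cm)

    def test_matches_vertex_enumeration(self, symmetric_community, asymmetric_community):
        for cm, expected in ((symmetric_community, 10.0), (asymmetric_community, 6.0)):
            S, met_index, rxn_index, lb, ub = cm.to_matrices()
            # bound the env secretion so enumeration stays finite
            dense = S.toarray()
            ub = np.where(np.isinf(ub), 1000.0, ub)
            oracle = lp_extreme(cm.objective_vector(), dense, lb, ub, sense="max")
            assert oracle == pytest.approx(expected, abs=1e-9)
            mu, _ = maximize_community_growth(cm)
            assert mu == pytest.approx(oracle, abs=1e-9)


class TestStage2:
    def test_symmetric_allocation(self, symmetric_community):
        tr = cooperative_tradeoff(symmetric_community, 0.5)
        assert tr.member_growth["A"] == pytest.approx(5.0, abs=1e-9)
        assert tr.member_growth["B"] == pytest.approx(5.0, abs=1e-9)

    def test_asymmetric_allocation(self, asymmetric_community):
        tr = cooperative_tradeoff(asymmetric_community, 0.5)
        assert tr.member_growth["A"] == pytest.approx(4.0, abs=1e-9)
        assert tr.member_growth["B"] == pytest.approx(2.0, abs=1e-9)
        ssq = sum(v**2 for v in tr.member_growth.values())
        assert ssq == pytest.approx(20.0, abs=1e-8)

    def test_full_fraction_forces_optimum(self, asymmetric_community):
        tr = cooperative_tradeoff(asymmetric_community, 1.0)
        assert tr.member_growth["A"] == pytest.approx(10.0, abs=1e-9)
        assert tr.member_growth["B"] == pytest.approx(2.0, abs=1e-9)

    def test_invalid_fraction_rejected(self, symmetric_community):
        for f in (0.0, -0.5, 1.5):
            with pytest.raises(ValidationError):
                cooperative_tradeoff(symmetric_community, f)

    def test_stage_ordering(self, scenario_communities):
        for cm in scenario_communities.values():
            for f in (0.3, 0.7, 1.0):
                tr = cooperative_tradeoff(cm, f)
                growth = tr.community_growth(cm.abundances)
                assert growth >= f * tr.mu_star - 1e-9

    def test_ssq_monotone_in_f(self, scenario_communities):
        cm = scenario_communities["Ac50/CO2_50"]
        prev = -1.0
        for f in (0.2, 0.4, 0.6, 0.8, 1.0):
            tr = cooperative_tradeoff(cm, f)
            ssq = sum(v**2 for v in tr.member_growth.values())
            assert ssq >= prev - 1e-8
            prev = ssq

    def test_abundance_weighted_variant(self, asymmetric_community):
        tr = cooperative_tradeoff(
            asymmetric_community, 0.5, weights=asymmetric_community.abundances
        )
        growth = tr.community_growth(asymmetric_community.abundances)
        assert growth >= 0.5 * tr.mu_star - 1e-9


class TestStage3:
    def test_symmetric_minimal_uptake(self, symmetric_community):
        tr = cooperative_tradeoff(symmetric_community, 0.5)
        sol = parsimonious_exchange_solution(symmetric_community, tr)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_zero_growth_zero_exchange(self, symmetric_community):
        cm = apply_medium(symmetric_community, Medium({}))
        mu, _ = maximize_community_growth(cm)
        assert mu == 0.0
        tr = cooperative_tradeoff(cm, 0.5)
        sol = parsimonious_exchange_solution(cm, tr)
        env = [
            sol.fluxes[r.id]
            for r in cm.reactions.values()
            if r.kind == "env_exchange"
        ]
        assert all(v == 0.0 for v in env)

    def test_redundant_route_same_total(self):
        """A second, interconvertible substrate leaves the minimum unchanged."""

        def member(mid):
            return MetabolicModel(
                id=mid,
                metabolites=[
                    Metabolite("s_e", "s", "e"),
                    Metabolite("t_e", "t", "e"),
                ],
                reactions=[
                    Reaction("EX_s", {"s_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
                    Reaction("EX_t", {"t_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
                    Reaction("conv", {"t_e": -1.0, "s_e": 1.0}, 0.0, 1000.0),
                    Reaction("growth", {"s_e": -1.0}, 0.0, 10.0),
                ],
                genes=[],
                objective_reaction_id="growth",
            )

        cm = build_community(
            [MemberSpec(member("A"), 0.5), MemberSpec(member("B"), 0.5)]
        )
        cm = apply_medium(cm, Medium({"s": 10.0, "t": 10.0}))
        tr = cooperative_tradeoff(cm, 0.5)
        sol = parsimonious_exchange_solution(cm, tr)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_matches_orthant_vertex_enumeration(self, asymmetric_community):
        cm = asymmetric_community
        tr = cooperative_tradeoff(cm, 0.5)
        sol = parsimonious_exchange_solution(cm, tr)
        S, met_index, rxn_index, lb, ub = cm.to_matrices()
        lb, ub = lb.copy(), np.where(np.isinf(ub), 1000.0, ub)
        for m, col in (("A", rxn_index["A__growth"]), ("B", rxn_index["B__growth"])):
            lb[col] = ub[col] = tr.member_growth[m]
        env_cols = [
            rxn_index[r.id] for r in cm.reactions.values() if r.kind == "env_exchange"
        ]
        oracle = min_abs_sum(S.toarray(), lb, ub, env_cols)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_mass_balance_residual(self, scenario_communities):
        for cm in scenario_communities.values():
            tr = cooperative_tradeoff(cm, 0.5)
            sol = parsimonious_exchange_solution(cm, tr)
            S, *_ = cm.to_matrices()
            v = np.array([sol.raw_fluxes[rid] for rid in cm.reactions])
            assert np.abs(S @ v).max() <= 1e-6

    def test_reported_fluxes_rounded(self, scenario_communities):
        cm = scenario_communities["CO2_100"]
        tr = cooperative_tradeoff(cm, 0.5)
        sol = parsimonious_exchange_solution(cm, tr)
        for v in sol.fluxes.values():
            assert v == 0.0 or abs(v) >= FLUX_TOLERANCE

    def test_uptake_monotone_in_f(self, scenario_communities):
        cm = scenario_communities["CO2_100"]
        prev = -1.0
        for f in (0.25, 0.5, 0.75, 1.0):
            tr = cooperative_tradeoff(cm, f)
            sol = parsimonious_exchange_solution(cm, tr)
            assert sol.objective_value >= prev - 1e-8
            prev = sol.objective_value


class TestMinimalMedium:
    def test_symmetric_toy(self, symmetric_community):
        tr = cooperative_tradeoff(symmetric_community, 0.5)
        mm = minimal_medium(symmetric_community, tr)
        assert set(mm.uptake) == {"s"}
        assert mm.uptake["s"] == pytest.approx(5.0, abs=1e-9)

    def test_methanogen_alone_h2_co2(self, toy_members):
        cm = build_community([MemberSpec(toy_members["methanogen"], 1.0)])
        cm = apply_medium(cm, Medium({"h2": 40.0, "co2": 10.0}))
        tr = cooperative_tradeoff(cm, 1.0)
        mm = minimal_medium(cm, tr)
        assert set(mm.uptake) == {"h2", "co2"}

    def test_removal_makes_infeasible(self, toy_members):
        cm = build_community([MemberSpec(toy_members["methanogen"], 1.0)])
        cm = apply_medium(cm, Medium({"h2": 40.0, "co2": 10.0}))
        tr = cooperative_tradeoff(cm, 1.0)
        mm = minimal_medium(cm, tr)
        for met in mm.uptake:
            reduced = cm.copy()
            reduced.reactions[f"EX_{met}"].lower_bound = 0.0
            with pytest.raises(OptimizationError):
                parsimonious_exchange_solution(reduced, tr)


class TestFluxRange:
    def test_determined_reaction_degenerate_range(self, symmetric_community):
        tr = cooperative_tradeoff(symmetric_community, 0.5)
        lo, hi = flux_range(symmetric_community, "A__growth", tr, delta=0.0)
        assert lo == pytest.approx(hi, abs=1e-8)

    def test_formate_export_favoured_under_acetate(self, scenario_communities):
        cm = scenario_communities["Ac90/CO2_10"]
        tr = cooperative_tradeoff(cm, 0.5)
        lo, hi = flux_range(cm, "rg_bacterium__EX_for", tr)
        assert (lo + hi) / 2.0 > 0.0

    def test_contains_parsimonious_value(self, scenario_communities):
        cm = scenario_communities["Ac50/CO2_50"]
        tr = cooperative_tradeoff(cm, 0.5)
        sol = parsimonious_exchange_solution(cm, tr)
        for rid in ("methanogen__fdh", "EX_co2", "rg_bacterium__rg"):
            lo, hi = flux_range(cm, rid, tr)
            assert lo - 1e-6 <= sol.raw_fluxes[rid] <= hi + 1e-6

    def test_unknown_reaction_rejected(self, symmetric_community):
        tr = cooperative_tradeoff(symmetric_community, 0.5)
        with pytest.raises(ValidationError):
            flux_range(symmetric_community, "missing", tr)


class TestReduction:
    def test_single_member_f1_reduces_to_fba(self, toy_members):
        """a = 1, f = 1: community ctFBA equals plain FBA on the member."""
        model = toy_members["rg_bacterium"]
        cm = build_community([MemberSpec(model, 1.0)])
        cm = apply_medium(cm, Medium({"ac": 6.0, "h2o": 1000.0}))
        tr = cooperative_tradeoff(cm, 1.0)
        mu_fba, _ = fba_max(
            model,
            fixed={
                "EX_ac": (-6.0, 1000.0),
                "EX_for": (0.0, 1000.0),
                "EX_h2": (0.0, 1000.0),
                "EX_co2": (0.0, 1000.0),
                "EX_h2o": (-1000.0, 1000.0),
            },
        )
        assert tr.member_growth["rg_bacterium"] == pytest.approx(mu_fba, abs=1e-9)
        sol = parsimonious_exchange_solution(cm, tr)
        assert sol.community_growth == pytest.approx(mu_fba, abs=1e-6)


class TestWriters:
    def test_solution_writers(self, tmp_path, symmetric_community):
        import json

        import pandas as pd

        tr = cooperative_tradeoff(symmetric_community, 0.5)
        sol = parsimonious_exchange_solution(symmetric_community, tr)
        write_solution_tsv(sol, symmetric_community, tmp_path / "fluxes.tsv")
        df = pd.read_csv(tmp_path / "fluxes.tsv", sep="\t")
        assert set(df.columns) == {"reaction", "member", "metabolite", "flux"}
        assert len(df) == len(symmetric_community.reactions)
        write_summary_json(tr, sol, tmp_path / "summary.json")
        payload = json.loads((tmp_path / "summary.json").read_text())
        assert payload["mu_star"] == pytest.approx(10.0)
        assert payload["f"] == 0.5
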