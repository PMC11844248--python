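import numpy as np
import pytest

from commflux.community import MemberSpec, Medium, apply_medium, build_community
from commflux.gem_core import MetabolicModel, Metabolite, Reaction
from commflux.synthetic_data import (
    DEFAULT_ABUNDANCES,
    MAIN_SCENARIOS,
    make_benchmark,
    make_scenario,
    make_toy_member,
    scenario_medium_for_community,
)


def substrate_member(member_id: str, growth_ub: float = 10.0) -> MetabolicModel:
    """One-substrate member: uptake s, grow with yield 1, growth <= ub."""
    return MetabolicModel(
        id=member_id,
        metabolites=[Metabolite("s_e", "substrate", "e")],
        reactions=[
            Reaction("EX_s", {"s_e": -1.0}, -1000.0, 1000.0, is_exchange=True),
            Reaction("growth", {"s_e": -1.0}, 0.0, growth_ub),
        ],
        genes=[],
        objective_reaction_id="growth",
    )


@pytest.fixture
def symmetric_community():
    cm = build_community(
        [MemberSpec(substrate_member("A"), 0.5), MemberSpec(substrate_member("B"), 0.5)]
    )
    return apply_medium(cm, Medium({"s": 10.0}))


@pytest.fixture
def asymmetric_community():
    cm = build_community(
        [
            MemberSpec(substrate_member("A"), 0.5),
            MemberSpec(substrate_member("B", growth_ub=2.0), 0.5),
        ]
    )
    return apply_medium(cm, Medium({"s": 10.0}))


@pytest.fixture(scope="session")
def toy_members():
    return {name: make_toy_member(name) for name in DEFAULT_ABUNDANCES}


@pytest.fixture(scope="session")
def scenario_communities(toy_members):
    """Three-member community under each main feeding scenario."""
    base = build_community(
        [MemberSpec(toy_members[m], a) for m, a in DEFAULT_ABUNDANCES.items()]
    )
    return {
        label: apply_medium(
            base, scenario_medium_for_community(make_scenario(label, 10.0))
        )
        for label in MAIN_SCENARIOS
    }


@pytest.fixture(scope="session")
def benchmark():
    return make_benchmark(seed=1)


def random_community(rng: np.random.Generator):
    """Seeded random small community for invariant sweeps."""
    names = list(DEFAULT_ABUNDANCES)
    k = int(rng.integers(2, 4))
    chosen = list(rng.choice(names, size=k, replace=False))
    raw = rng.dirichlet(np.ones(k) * 2.0)
    raw = np.maximum(raw, 0.02)
    raw = raw / raw.sum()
    members = [MemberSpec(make_toy_member(n), float(a)) for n, a in zip(chosen, raw)]
    label = MAIN_SCENARIOS[int(rng.integers(0, len(MAIN_SCENARIOS)))]
    c_tot = float(rng.uniform(5.0, 15.0))
    cm = build_community(members, abundance_threshold=0.01)
    return apply_medium(
        cm, scenario_medium_for_community(make_scenario(label, c_tot))
    )
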