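import math

import numpy as np
import pytest

import panefm as pf
from panefm.network import Environment, MetabolicNetwork, Reaction


@pytest.fixture(scope="session")
def toy() -> MetabolicNetwork:
    return pf.build_toy_model()


@pytest.fixture(scope="session")
def rich() -> Environment:
    return pf.toy_rich_environment()


@pytest.fixture(scope="session")
def pa_envs():
    """All 512 presence/absence environments of the toy compounds."""
    return pf.toy_presence_absence_environments()


@pytest.fixture(scope="session")
def growth_envs(toy, pa_envs):
    idx = pf.growth_supporting_environments(toy, pa_envs)
    return [pa_envs[i] for i in idx]


@pytest.fixture(scope="session")
def toy_minimal_sets(toy, rich):
    return pf.enumerate_minimal_functional_sets(toy, rich)


@pytest.fixture(scope="session")
def toy_exhaustive(toy, pa_envs):
    """Every minimal set of every growth-supporting environment, with usage."""
    return pf.exhaustive_collection(toy, pa_envs)


@pytest.fixture(scope="session")
def strains():
    return pf.toy_strain_reactomes()


def linear_chain_network(uptake_bound: float = 5.0) -> MetabolicNetwork:
    """EX_A (bound 5) -> A_i -> biomass: flux forced by the uptake bound."""
    return MetabolicNetwork(
        [
            Reaction("EX_A_e", {"A_e": -1}, -uptake_bound, 1000, is_exchange=True),
            Reaction("T_A", {"A_e": -1, "A_i": 1}),
            Reaction("biomass", {"A_i": -1}),
        ],
        "biomass",
        id="chain",
    )


@pytest.fixture
def chain() -> MetabolicNetwork:
    return linear_chain_network()


@pytest.fixture
def chain_env() -> Environment:
    return Environment({"A_e": math.inf})


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def greedy_oracle(minimal_sets, deletable, rng):
    """Independent panEFM sampler: greedy deletion where functionality is the
    purely combinatorial condition 'still contains at least one minimal set'
    (no linear programming involved)."""
    kept = set(deletable)
    for rid in rng.permutation(sorted(kept)):
        trial = kept - {rid}
        if any(s <= trial for s in minimal_sets):
            kept = trial
    return frozenset(kept)
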