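import numpy as np
import pytest

from spatialsir.network import ModelParams, SpatialModularNetwork, build_network


@pytest.fixture(scope="session")
def small_params() -> ModelParams:
    """A 4x4 community grid small enough for fast replicated runs."""
    return ModelParams(L=40, zeta=10, k_intra=3.0, k_inter=0.05)


@pytest.fixture(scope="session")
def small_net(small_params) -> SpatialModularNetwork:
    return build_network(small_params, seed=1234)


@pytest.fixture(scope="session")
def medium_net() -> SpatialModularNetwork:
    """10x10 grid of 100-node cities, the workhorse for statistical checks."""
    params = ModelParams(L=100, zeta=10, k_intra=4.0, k_inter=0.1)
    return build_network(params, seed=77)


def path_graph(n: int) -> SpatialModularNetwork:
    return SpatialModularNetwork.from_edges(n, [(i, i + 1) for i in range(n - 1)])


@pytest.fixture(scope="session")
def path3() -> SpatialModularNetwork:
    return path_graph(3)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
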