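from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from obstaccess.network import RoadNetwork
from obstaccess.synthetic_benchmark import BenchmarkRegion, build_benchmark_region


def make_path_network(weights: list[float]) -> RoadNetwork:
    """Path graph 0—1—2—… with the given edge travel times and unit spacing."""
    g = nx.Graph()
    for i in range(len(weights) + 1):
        g.add_node(i, x=float(i), y=0.0)
    for i, w in enumerate(weights):
        g.add_edge(i, i + 1, time=float(w))
    return RoadNetwork(g)


@pytest.fixture(scope="session")
def benchmark_region() -> BenchmarkRegion:
    return build_benchmark_region()


@pytest.fixture(scope="session")
def recovery_200():
    """200-replicate parameter-recovery experiment at n=702 (shared: it is
    the expensive study-scale simulation)."""
    from obstaccess.experiments import run_recovery

    return run_recovery(n_replicates=200, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
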