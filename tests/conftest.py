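import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lagnet import RegulatoryNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path_abc() -> RegulatoryNetwork:
    """The directed path a -> b -> c (the standard tiny worked example)."""
    return RegulatoryNetwork.from_edge_list("abc", [("a", "b"), ("b", "c")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def network_from_indices(n: int, edges: set[tuple[int, int]]) -> RegulatoryNetwork:
    """Integer-indexed edge set -> RegulatoryNetwork over genes n0..n{n-1}."""
    ids = tuple(f"n{k}" for k in range(n))
    return RegulatoryNetwork(ids, {(ids[i], ids[j]): None for i, j in edges})
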