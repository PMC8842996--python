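import numpy as np
import pytest

from hiaerpart import HierarchySpec, NeuronGraph


@pytest.fixture
def spec22() -> HierarchySpec:
    return HierarchySpec((2, 2))


@pytest.fixture
def spec48() -> HierarchySpec:
    return HierarchySpec((4, 8))


def random_graph(n: int, n_synapses: int, seed: int) -> NeuronGraph:
    """Uniform random directed graph without self-loops (test helper)."""
    rng = np.random.default_rng(seed)
    pre = rng.integers(0, n, size=n_synapses)
    post = rng.integers(0, n, size=n_synapses)
    loop = pre == post
    post[loop] = (post[loop] + 1) % n
    return NeuronGraph(n_neurons=n, pre=pre, post=post)
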