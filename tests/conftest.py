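import numpy as np
import pandas as pd
import pytest

import grouprank as gr
from grouprank.expression import CASE, CONTROL


@pytest.fixture
def triangle_net():
    return gr.PPINetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def edge_net():
    return gr.PPINetwork.from_edges([("A", "B")])


def make_expr(values: np.ndarray, genes, n_case: int, n_control: int):
    """Build an ExpressionMatrix from a raw array (cases first)."""
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_control)
    ]
    labels = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    return gr.ExpressionMatrix(
        values=pd.DataFrame(values, index=list(genes), columns=samples),
        labels=labels,
    )


@pytest.fixture
def small_expr():
    """4 genes x 6 samples; gene g1 strongly shifted, g4 flat."""
    rng = np.random.default_rng(0)
    X = rng.normal(8, 0.3, size=(4, 6))
    X[0, :3] += 5.0          # g1 up in cases
    X[3, :] = 7.0            # g4 constant
    return make_expr(X, ["g1", "g2", "g3", "g4"], 3, 3)


@pytest.fixture(scope="session")
def default_instance():
    """One default-condition synthetic instance shared across tests."""
    return gr.make_instance(seed=11)


@pytest.fixture(scope="session")
def default_pipeline(default_instance):
    """DE result, kernel and groups (d = 0.3) for the shared instance."""
    inst = default_instance
    de = gr.de_test(inst.expression)
    S = gr.kernel_for_network(inst.network)
    de_genes = [g for g in de.de_genes if g in inst.network]
    dist = gr.correlation_distance(inst.expression, de_genes)
    groups = gr.cluster_groups(dist, 0.3, de=de)
    return de, S, groups


def random_network(n_nodes: int, p: float, seed: int) -> gr.PPINetwork:
    """Erdos-Renyi-style random network over letter-coded gene names."""
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return gr.PPINetwork.from_edges(edges, nodes=nodes)
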