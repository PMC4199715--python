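"""Synthetic benchmark instances: network, planted modules, expression.

The generator emulates the three inputs the pipeline needs with a known
ground truth:

* a scale-free-ish PPI stand-in (preferential attachment by default),
* designated "disease genes" whose network neighborhoods contain planted
  modules of coordinately differentially expressed, mutually correlated
  genes,
* a log2-scale expression matrix in which module genes share a per-module
  latent factor (inducing equicorrelation ~ rho) and a class-mean shift of
  ``effect`` log2 units in cases, while background genes are independent
  noise.

By default the disease genes themselves receive background expression: the
signal a ranking method can exploit is purely their network proximity to the
planted modules, which is exactly the premise the ranking score encodes.

All randomness flows from one master seed through ``numpy.random
.SeedSequence`` children, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, ExpressionMatrix
from .network import PPINetwork

logger = logging.getLogger(__name__)

#: default synthetic study conditions
DEFAULTS = dict(
    n_nodes=200,
    n_disease_genes=3,
    module_size=8,
    hop_radius=1,
    n_case=10,
    n_control=10,
    effect=2.0,
    rho=0.85,
    noise_sd=0.5,
    baseline=8.0,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic instance."""

    disease_genes: list[str]
    modules: dict[str, list[str]]       # disease gene -> module members
    module_signs: dict[str, int] = field(default_factory=dict)
    effect: float = float("nan")
    rho: float = float("nan")

    @property
    def module_genes(self) -> list[str]:
        return [g for members in self.modules.values() for g in members]


@dataclass
class SyntheticInstance:
    network: PPINetwork
    expression: ExpressionMatrix
    truth: SyntheticTruth
    seed: int


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_network(
    n_nodes: int = DEFAULTS["n_nodes"],
    model: str = "preferential-attachment",
    seed: int | None = None,
    m: int = 3,
) -> PPINetwork:
    """Random connected graph with heavy-tailed degrees.

    "preferential-attachment" uses the Barabasi-Albert process with ``m``
    edges per new node (m = 3 gives a mean degree near that of curated human
    PPI networks); "configuration" draws a power-law degree sequence and
    keeps the largest component if the multigraph simplifies to a
    disconnected graph.
    """
    if n_nodes < 10:
        raise ValueError("need n_nodes >= 10")
    if model == "preferential-attachment":
        G = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "configuration":
        rng = np.random.default_rng(seed)
        while True:
            deg = rng.zipf(2.3, size=n_nodes)
            deg = np.minimum(deg, n_nodes // 4)
            if deg.sum() % 2 == 0:
                break
        G = nx.Graph(nx.configuration_model(deg.tolist(), seed=int(
            rng.integers(2**31))))
        G.remove_edges_from(nx.selfloop_edges(G))
        if not nx.is_connected(G):
            largest = max(nx.connected_components(G), key=len)
            logger.info("configuration model disconnected; keeping largest "
                        "component (%d / %d nodes)", len(largest), n_nodes)
            G = G.subgraph(largest).copy()
    else:
        raise ValueError(f"unknown network model {model!r}")
    mapping = {old: _gene_name(i) for i, old in enumerate(sorted(G.nodes()))}
    G = nx.relabel_nodes(G, mapping)
    nodes = sorted(G.nodes())
    edges = sorted((min(a, b), max(a, b)) for a, b in G.edges())
    return PPINetwork.from_edges(edges, nodes=nodes)


def plant_modules(
    net: PPINetwork,
    n_disease_genes: int = DEFAULTS["n_disease_genes"],
    module_size: int = DEFAULTS["module_size"],
    hop_radius: int = DEFAULTS["hop_radius"],
    seed: int | None = None,
    hub_cap: float = 15.0,
    disjoint: bool = True,
) -> SyntheticTruth:
    """Choose disease genes and plant a module in each one's neighborhood.

    Disease genes are drawn from mid-degree nodes (neighborhood large enough
    to host the module, degree at most ``hub_cap`` so the planted signal is
    not confounded with trivially penalized hubs).  Module members are
    sampled from the <= hop_radius neighborhood *excluding* the disease gene
    itself, so proximity — not the gene's own expression — carries the
    signal.
    """
    rng = np.random.default_rng(seed)
    G = nx.from_numpy_array(net.adjacency)
    idx_to_gene = dict(enumerate(net.nodes))

    neighborhoods: dict[str, list[str]] = {}
    for i, gene in idx_to_gene.items():
        ball = nx.single_source_shortest_path_length(G, i,
                                                     cutoff=hop_radius)
        neighborhoods[gene] = sorted(
            idx_to_gene[j] for j in ball if j != i
        )

    degree = {g: net.degree_of(g) for g in net.nodes}
    eligible = [
        g for g in net.nodes
        if len(neighborhoods[g]) >= module_size and degree[g] <= hub_cap
    ]
    if len(eligible) < n_disease_genes:
        raise ValueError(
            f"only {len(eligible)} nodes can host a module of size "
            f"{module_size} within {hop_radius} hop(s); reduce module_size "
            f"or increase hop_radius"
        )

    disease = list(rng.choice(eligible, size=n_disease_genes, replace=False))
    modules: dict[str, list[str]] = {}
    signs: dict[str, int] = {}
    used: set[str] = set(disease)
    for g in disease:
        pool = neighborhoods[g]
        if disjoint:
            free = [x for x in pool if x not in used]
            pool = free if len(free) >= module_size else pool
        members = sorted(rng.choice(pool, size=module_size, replace=False))
        modules[g] = members
        used.update(members)
        signs[g] = 1 if rng.random() < 0.5 else -1
    return SyntheticTruth(disease_genes=sorted(disease), modules=modules,
                          module_signs=signs)


def simulate_expression(
    net: PPINetwork,
    truth: SyntheticTruth,
    n_case: int = DEFAULTS["n_case"],
    n_control: int = DEFAULTS["n_control"],
    effect: float = DEFAULTS["effect"],
    rho: float = DEFAULTS["rho"],
    noise_sd: float = DEFAULTS["noise_sd"],
    baseline: float = DEFAULTS["baseline"],
    seed: int | None = None,
    disease_genes_de: bool = False,
) -> ExpressionMatrix:
    """Simulate a log2-scale expression matrix over the network genes.

    Background genes are i.i.d. normal(baseline, noise_sd) in both classes.
    Module genes share a per-module standard-normal latent factor weighted
    by sqrt(rho) (equicorrelation ~ rho within a module) plus independent
    noise weighted by sqrt(1 - rho), all scaled by ``noise_sd``, and cases
    get a class-mean shift of ``effect`` log2 units with the module's sign.
    Disease genes stay at background unless ``disease_genes_de`` is set.
    """
    if n_case < 3 or n_control < 3:
        raise ValueError("need >= 3 samples per class")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    genes = net.nodes
    gene_idx = {g: i for i, g in enumerate(genes)}
    is_case = np.r_[np.ones(n_case, bool), np.zeros(n_control, bool)]

    X = baseline + noise_sd * rng.standard_normal((len(genes), n_samples))
    for dg, members in truth.modules.items():
        factor = rng.standard_normal(n_samples)
        sign = truth.module_signs.get(dg, 1)
        targets = list(members) + ([dg] if disease_genes_de else [])
        for g in targets:
            i = gene_idx[g]
            noise = rng.standard_normal(n_samples)
            X[i] = baseline + noise_sd * (
                np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
            )
            X[i, is_case] += sign * effect

    samples = [f"case_{j + 1}" for j in range(n_case)] + [
        f"ctrl_{j + 1}" for j in range(n_control)
    ]
    values = pd.DataFrame(X, index=genes, columns=samples)
    labels = pd.Series(
        [CASE] * n_case + [CONTROL] * n_control, index=samples
    )
    truth.effect = effect
    truth.rho = rho
    return ExpressionMatrix(values=values, labels=labels)


def make_instance(seed: int = 0, **overrides) -> SyntheticInstance:
    """Generate a full synthetic instance under the default study conditions.

    One master seed fans out to independent child seeds for the network,
    the module placement, and the expression simulation.
    """
    cfg = dict(DEFAULTS)
    disease_genes_de = bool(overrides.pop("disease_genes_de", False))
    model = overrides.pop("model", "preferential-attachment")
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise TypeError(f"unknown parameters: {sorted(unknown)}")
    cfg.update(overrides)

    s_net, s_plant, s_expr = np.random.SeedSequence(seed).spawn(3)

    def child(ss) -> int:
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    net = make_network(cfg["n_nodes"], model=model, seed=child(s_net))
    truth = plant_modules(
        net, cfg["n_disease_genes"], cfg["module_size"], cfg["hop_radius"],
        seed=child(s_plant),
    )
    expr = simulate_expression(
        net, truth, cfg["n_case"], cfg["n_control"], cfg["effect"],
        cfg["rho"], cfg["noise_sd"], cfg["baseline"], seed=child(s_expr),
        disease_genes_de=disease_genes_de,
    )
    return SyntheticInstance(network=net, expression=expr, truth=truth,
                             seed=seed)


def write_instance(instance: SyntheticInstance, outdir) -> dict[str, Path]:
    """Write edge list, expression TSV, labels TSV and truth JSON.

    Files use exactly the formats the main pipeline reads back.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "network.tsv",
        "expr": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.json",
    }
    net = instance.network
    with open(paths["ppi"], "w") as fh:
        for i, j in zip(*np.nonzero(np.triu(net.adjacency))):
            fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\n")
    instance.expression.values.to_csv(paths["expr"], sep="\t",
                                      index_label="gene")
    instance.expression.labels.to_csv(paths["labels"], sep="\t", header=False)
    truth = instance.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": instance.seed,
                "disease_genes": truth.disease_genes,
                "modules": truth.modules,
                "module_signs": truth.module_signs,
                "effect": truth.effect,
                "rho": truth.rho,
            },
            fh, indent=2,
        )
    return paths
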