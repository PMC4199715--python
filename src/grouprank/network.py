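"""PPI network handling and the discrete diffusion-kernel similarity matrix.

The network is an undirected, unweighted graph over gene symbols.  From it we
build the row-stochastic random-walk transition matrix ``W = D^-1 A`` and the
discrete heat-diffusion kernel

    S = (I + (gamma / n_iter) * (W - I)) ** n_iter

which converges to ``exp(gamma * (W - I))`` as ``n_iter`` grows.  ``S[i, j]``
is read as the similarity *from* candidate ``i`` *to* gene ``j``; since the
adjacency is symmetric the distinction only matters around hubs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: tokens that mark an optional header line in an edge-list file
DEFAULT_HEADER_KEYWORDS = frozenset(
    {"gene_a", "gene_b", "genea", "geneb", "protein1", "protein2",
     "source", "target", "symbol_a", "symbol_b"}
)

#: node count above which the kernel is computed with sparse matrix powers
DENSE_NODE_LIMIT = 20_000


class NetworkError(ValueError):
    """Raised for malformed or empty network inputs."""


@dataclass
class PPINetwork:
    """Undirected PPI graph with a fixed node order.

    Attributes
    ----------
    nodes:
        Gene symbols in first-appearance order; defines the row/column order
        of every matrix derived from the network.
    adjacency:
        Dense binary symmetric matrix with zero diagonal.
    """

    nodes: list[str]
    adjacency: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise NetworkError("adjacency shape does not match node count")
        if not np.array_equal(A, A.T):
            raise NetworkError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise NetworkError("adjacency must have a zero diagonal")
        self.adjacency = A
        self.index = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise NetworkError("duplicate node symbols")

    @classmethod
    def from_edges(cls, edges, nodes: list[str] | None = None) -> "PPINetwork":
        """Build a network from an iterable of (a, b) symbol pairs.

        Self-loops are dropped and duplicate edges (in either orientation)
        are collapsed.  Node order is first-appearance order in the edge
        stream unless an explicit ``nodes`` list is given.
        """
        order: list[str] = list(nodes) if nodes is not None else []
        seen = set(order)
        pairs: set[frozenset[str]] = set()
        for a, b in edges:
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    order.append(g)
            if a == b:
                continue
            pairs.add(frozenset((a, b)))
        if not order:
            raise NetworkError("empty network: no nodes")
        idx = {g: i for i, g in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for pair in pairs:
            a, b = tuple(pair)
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
        return cls(nodes=order, adjacency=A)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degree(self) -> np.ndarray:
        """Per-node degree k, the row sum of the adjacency matrix."""
        return self.adjacency.sum(axis=1)

    def degree_of(self, gene: str) -> float:
        return float(self.degree[self.index[gene]])

    def neighbors(self, gene: str) -> list[str]:
        row = self.adjacency[self.index[gene]]
        return [self.nodes[j] for j in np.flatnonzero(row)]

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def content_hash(self) -> str:
        """Stable hash of the edge set, for caching kernels."""
        h = hashlib.sha256()
        for g in self.nodes:
            h.update(g.encode())
            h.update(b"\x00")
        h.update(np.ascontiguousarray(self.adjacency, dtype=np.uint8).tobytes())
        return h.hexdigest()


def load_ppi(path, header_keywords=DEFAULT_HEADER_KEYWORDS) -> PPINetwork:
    """Read a two-column whitespace/tab edge list into a :class:`PPINetwork`.

    Lines starting with ``#`` are skipped; extra columns beyond the first two
    are ignored; an initial header line is auto-detected when either of its
    first two tokens (lower-cased) appears in ``header_keywords``.
    """
    edges: list[tuple[str, str]] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise NetworkError(
                    f"{path}: malformed line {lineno}: expected at least two "
                    f"columns, got {len(tokens)}"
                )
            a, b = tokens[0], tokens[1]
            if n_lines == 0 and (
                a.lower() in header_keywords or b.lower() in header_keywords
            ):
                n_lines += 1
                continue
            n_lines += 1
            edges.append((a, b))
    if not edges:
        raise NetworkError(f"{path}: empty network (no valid edges)")
    net = PPINetwork.from_edges(edges)
    n_dupes = len(edges) - net.n_edges - sum(1 for a, b in edges if a == b)
    logger.info(
        "loaded PPI network: %d nodes, %d edges (%d duplicate, %d self-loop "
        "lines dropped)",
        net.n_nodes, net.n_edges, n_dupes,
        sum(1 for a, b in edges if a == b),
    )
    return net


def transition_matrix(net: PPINetwork) -> np.ndarray:
    """Row-stochastic random-walk matrix ``W = D^-1 A``.

    Rows of isolated nodes (degree 0) are all zero: no renormalization or
    teleportation is invented for them.
    """
    if net.n_nodes == 0:
        raise NetworkError("empty network")
    k = net.degree
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(k[:, None] > 0, net.adjacency / k[:, None], 0.0)
    return W


@dataclass
class SimilarityMatrix:
    """Dense diffusion-kernel similarity over a fixed node order."""

    S: np.ndarray
    gamma: float
    n_iter: int
    W: np.ndarray
    nodes: list[str] | None = None
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = (
            {g: i for i, g in enumerate(self.nodes)} if self.nodes else {}
        )

    def between(self, gene_from: str, gene_to: str) -> float:
        """Similarity from a candidate gene to a group-member gene."""
        return float(self.S[self.index[gene_from], self.index[gene_to]])


def diffusion_kernel(
    W: np.ndarray,
    gamma: float = 1.0,
    n_iter: int = 5,
    nodes: list[str] | None = None,
) -> SimilarityMatrix:
    """Discrete heat-diffusion kernel ``S = (I + (gamma/n_iter)(W - I))^n_iter``.

    Parameters
    ----------
    W:
        Row-stochastic transition matrix (dense or scipy sparse).
    gamma:
        Diffusion rate; larger values diffuse mass further per iteration.
    n_iter:
        Number of iterations; small values (~5) already approximate the
        continuous kernel ``exp(gamma (W - I))`` well.

    Tiny negative entries from floating-point cancellation are clipped to 0.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if int(n_iter) < 1 or n_iter != int(n_iter):
        raise ValueError(f"n_iter must be a positive integer, got {n_iter}")
    n_iter = int(n_iter)

    sparse_in = sp.issparse(W)
    n = W.shape[0]
    if not sparse_in and n > DENSE_NODE_LIMIT:
        W = sp.csr_matrix(W)
        sparse_in = True

    if sparse_in:
        M = sp.identity(n, format="csr") + (gamma / n_iter) * (
            sp.csr_matrix(W) - sp.identity(n, format="csr")
        )
        S = _sparse_matrix_power(M, n_iter).toarray()
        W_dense = sp.csr_matrix(W).toarray()
    else:
        W_dense = np.asarray(W, dtype=float)
        M = np.eye(n) + (gamma / n_iter) * (W_dense - np.eye(n))
        S = np.linalg.matrix_power(M, n_iter)
    np.clip(S, 0.0, None, out=S)
    return SimilarityMatrix(S=S, gamma=gamma, n_iter=n_iter, W=W_dense,
                            nodes=nodes)


def kernel_for_network(
    net: PPINetwork, gamma: float = 1.0, n_iter: int = 5
) -> SimilarityMatrix:
    """Convenience wrapper: transition matrix + kernel with node labels."""
    return diffusion_kernel(
        transition_matrix(net), gamma=gamma, n_iter=n_iter, nodes=net.nodes
    )


def _sparse_matrix_power(M: sp.csr_matrix, p: int) -> sp.csr_matrix:
    result = sp.identity(M.shape[0], format="csr")
    base = M.copy()
    while p:
        if p & 1:
            result = result @ base
        p >>= 1
        if p:
            base = base @ base
    return result
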