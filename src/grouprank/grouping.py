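"""Partition DE genes into co-expressed groups by hierarchical clustering.

Pairwise gene distance is ``d_ij = (1 - r_ij) / 2`` where ``r_ij`` is the
Pearson correlation of the two expression profiles over all samples; this
maps r in [-1, 1] onto d in [0, 1] so the full sweep range of the cut
threshold covers the full correlation range, with anti-correlated genes
maximally distant.  An unsigned variant ``d = 1 - |r|`` is available.
Clustering is agglomerative with average linkage (UPGMA), cut at height d.
Genes are sorted lexicographically before clustering so the partition is
invariant to input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class GeneGroup:
    """A co-expressed DE gene cluster.

    ``e`` is the group differential-expression level (geometric mean of
    |log2 ratio| over members); ``sign`` records the dominant regulation
    direction as metadata.
    """

    members: list[str]
    e: float = float("nan")
    sign: int = 0
    group_id: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a gene group must have >= 1 member")
        self.members = list(self.members)

    @property
    def n(self) -> int:
        return len(self.members)


def correlation_distance(
    expr, genes, mode: str = "signed"
) -> pd.DataFrame:
    """Pairwise correlation distance among ``genes`` over all samples.

    mode="signed" gives ``(1 - r) / 2`` (default); mode="abs" gives
    ``1 - |r|``.  A zero-variance gene has undefined correlations and is
    assigned the maximal distance 1 to every partner (with a warning).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for pairwise distances")
    X = expr.values.loc[genes].to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples per gene for correlation")
    if mode not in ("signed", "abs"):
        raise ValueError(f"unknown distance mode {mode!r}")

    flat = X.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    D = (1.0 - r) / 2.0 if mode == "signed" else 1.0 - np.abs(r)
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s): correlation undefined, assigned "
            "maximal distance", int(flat.sum()),
        )
        D[flat, :] = 1.0
        D[:, flat] = 1.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against floating-point noise
    return pd.DataFrame(D, index=genes, columns=genes)


def cluster_groups(
    dist: pd.DataFrame,
    d: float,
    de=None,
    drop_singletons: bool = False,
) -> list[GeneGroup]:
    """Cut an average-linkage tree at height ``d`` into :class:`GeneGroup`s.

    At d = 0 every gene is a singleton (no positive-distance merges); at
    d = 1 all genes whose cophenetic distances stay below 1 merge into one
    group.  If a :class:`~grouprank.expression.DEResult` is supplied, each
    group's expression level ``e`` is filled in.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"distance threshold must be in [0, 1], got {d}")
    genes = sorted(dist.index)
    if len(genes) == 1:
        groups = [GeneGroup(members=genes)]
    else:
        D = dist.loc[genes, genes].to_numpy(dtype=float)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        flat = hierarchy.fcluster(Z, t=d, criterion="distance")
        by_label: dict[int, list[str]] = {}
        for g, lab in zip(genes, flat):
            by_label.setdefault(int(lab), []).append(g)
        groups = [
            GeneGroup(members=sorted(members))
            for members in by_label.values()
        ]
    groups.sort(key=lambda grp: grp.members[0])
    if drop_singletons:
        groups = [g for g in groups if g.n > 1]
    for i, grp in enumerate(groups):
        grp.group_id = f"group_{i + 1}"
    if de is not None:
        from .scoring import group_expression_level

        for grp in groups:
            group_expression_level(grp, de)
    logger.info("clustering at d=%.2f: %d groups from %d genes",
                d, len(groups), len(genes))
    return groups


def dendrogram_newick(dist: pd.DataFrame) -> str:
    """Average-linkage dendrogram of the distance matrix as a Newick string."""
    genes = sorted(dist.index)
    D = dist.loc[genes, genes].to_numpy(dtype=float)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return genes[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({walk(left)}:{ld:.6g},{walk(right)}:{rd:.6g})"

    return walk(tree) + ";"


@dataclass
class GroupTable:
    """Tabular export of a grouping (group id, members, n, e)."""

    groups: list[GeneGroup] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": [g.group_id for g in self.groups],
                "n": [g.n for g in self.groups],
                "e": [g.e for g in self.groups],
                "members": [",".join(g.members) for g in self.groups],
            }
        )
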