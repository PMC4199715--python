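"""Score candidate genes against co-expressed DE groups and rank them.

A candidate's score from one group is

    R_G = s * e * min(1, alpha / k) * min(1, beta / n)

where ``s`` is the geometric mean of the diffusion-kernel similarities from
the candidate to each group member, ``e`` the group's differential-expression
level (geometric mean of member |log2 ratio|), ``k`` the candidate's network
degree and ``n`` the group size.  The multiplicative caps damp hub candidates
(k > alpha) and super-sized groups (n > beta) and are inactive otherwise; an
exponential variant ``exp(-k/alpha) * exp(-n/beta)`` is available.  The final
integrated score is the sum of R_G over all groups, with per-group
contributions retained for attribution.

The SingleRank baseline is the degenerate case in which every DE gene forms
its own singleton group; it shares this scoring code exactly, so GroupRank at
cluster threshold d = 0 coincides with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grouping import GeneGroup

logger = logging.getLogger(__name__)

#: floor applied to geometric-mean factors so one zero similarity or zero
#: log2 ratio suppresses a score without producing log(0)
EPSILON = 1e-12


@dataclass
class ScoringParams:
    """Tunable parameters of the ranking score.

    alpha: hub-penalization threshold on candidate degree k (default 15,
        roughly twice the mean degree of a curated human PPI network).
    beta: group-size-penalization threshold on group size n (default 20).
    gamma, n_iter: forwarded to the diffusion kernel.
    penalty: "cap" for min(1, alpha/k) * min(1, beta/n) (default) or "exp"
        for exp(-k/alpha) * exp(-n/beta).
    """

    alpha: float = 15.0
    beta: float = 20.0
    gamma: float = 1.0
    n_iter: int = 5
    penalty: str = "cap"
    eps: float = EPSILON

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.penalty not in ("cap", "exp"):
            raise ValueError(f"unknown penalty form {self.penalty!r}")


@dataclass
class RankingResult:
    """Ranked candidates with per-group score attribution.

    ``table`` columns: ``score``, ``rank`` (average-rank ties),
    ``rank_ratio`` (rank / number of ranked candidates); index is the
    candidate symbol in descending-score order.  ``contributions`` holds the
    per-group additive terms whose exact sum is the score.
    """

    table: pd.DataFrame
    contributions: pd.DataFrame
    groups: list[GeneGroup]
    unranked: list[str] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.table)

    def rank_of(self, gene: str) -> float:
        if gene not in self.table.index:
            raise KeyError(f"gene {gene!r} is not ranked")
        return float(self.table.at[gene, "rank"])

    def score_of(self, gene: str) -> float:
        return float(self.table.at[gene, "score"])

    def top_contributor(self, gene: str) -> tuple[str, float]:
        """Top-contributing group id and its share of the gene's score."""
        row = self.contributions.loc[gene]
        total = row.sum()
        gid = row.idxmax()
        share = float(row[gid] / total) if total > 0 else 0.0
        return str(gid), share


def _geometric_mean(values: np.ndarray, eps: float = EPSILON) -> float:
    floored = np.maximum(np.asarray(values, dtype=float), eps)
    return float(np.exp(np.mean(np.log(floored))))


def group_similarity(S, candidate: str, group: GeneGroup,
                     eps: float = EPSILON) -> float:
    """Geometric mean of kernel similarities from candidate to each member.

    Entries are floored at ``eps``, so a single unreachable member drives the
    similarity toward ``eps`` (effectively suppressing the group) instead of
    producing log(0).
    """
    if candidate not in S.index:
        raise KeyError(f"candidate {candidate!r} is not a network node")
    i = S.index[candidate]
    vals = np.array([S.S[i, S.index[g]] for g in group.members])
    return _geometric_mean(vals, eps)


def group_expression_level(group: GeneGroup, de,
                           eps: float = EPSILON) -> float:
    """Geometric mean of |log2 ratio| over group members.

    Magnitudes are used so a coordinately down-regulated group counts as much
    as an up-regulated one; the dominant sign is stored on the group as
    metadata.  The result is cached on ``group.e``.
    """
    ratios = de.table.loc[group.members, "log2_ratio"].to_numpy(dtype=float)
    group.e = _geometric_mean(np.abs(ratios), eps)
    group.sign = int(np.sign(np.sign(ratios).sum()))
    return group.e


def _penalties(k: np.ndarray, n: int, params: ScoringParams):
    k = np.asarray(k, dtype=float)
    if params.penalty == "cap":
        with np.errstate(divide="ignore"):
            pen_k = np.where(k > 0, np.minimum(1.0, params.alpha / np.maximum(k, 1e-300)), 1.0)
        pen_n = min(1.0, params.beta / n)
    else:
        pen_k = np.exp(-k / params.alpha)
        pen_n = float(np.exp(-n / params.beta))
    return pen_k, pen_n


def group_score(candidate: str, group: GeneGroup, S, net, de,
                params: ScoringParams | None = None) -> float:
    """Penalized score R_G of one candidate against one group."""
    params = params or ScoringParams()
    s = group_similarity(S, candidate, group, params.eps)
    e = group.e if np.isfinite(group.e) else group_expression_level(
        group, de, params.eps)
    k = net.degree_of(candidate)
    pen_k, pen_n = _penalties(np.array([k]), group.n, params)
    return float(s * e * pen_k[0] * pen_n)


def integrated_score(candidate: str, groups, S, net, de,
                     params: ScoringParams | None = None) -> float:
    """Sum of per-group scores R_G over all groups."""
    if not groups:
        raise ValueError("need >= 1 group")
    return float(sum(group_score(candidate, g, S, net, de, params)
                     for g in groups))


def rank_candidates(candidates, groups, S, net, de,
                    params: ScoringParams | None = None) -> RankingResult:
    """Score and rank candidates by descending integrated score.

    Candidates absent from the network are excluded from ranking and
    reported in ``unranked``.  Group members absent from the network are
    dropped from their group before scoring (a group with no network member
    is dropped entirely).  With no groups at all, every candidate scores 0
    and shares the average rank.
    """
    params = params or ScoringParams()
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    ranked = [c for c in candidates if c in net]
    unranked = [c for c in candidates if c not in net]
    if unranked:
        logger.warning("%d candidate(s) not in network, left unranked",
                       len(unranked))
    if not ranked:
        raise ValueError("no candidate is a network node")

    usable: list[GeneGroup] = []
    for grp in groups:
        present = [g for g in grp.members if g in net]
        if not present:
            logger.warning("group %s has no network member; dropped",
                           grp.group_id or "?")
            continue
        if len(present) < grp.n:
            grp = GeneGroup(members=present, group_id=grp.group_id,
                            sign=grp.sign)
        usable.append(grp)
    if not usable:
        logger.warning("no usable gene groups: all scores are 0")

    cand_idx = np.array([net.index[c] for c in ranked])
    logS = np.log(np.maximum(S.S, params.eps))
    k = net.degree[cand_idx]

    contrib = np.zeros((len(ranked), len(usable)))
    gids = []
    for j, grp in enumerate(usable):
        member_idx = np.array([net.index[g] for g in grp.members])
        s_vec = np.exp(logS[np.ix_(cand_idx, member_idx)].mean(axis=1))
        e = grp.e if np.isfinite(grp.e) else group_expression_level(
            grp, de, params.eps)
        pen_k, pen_n = _penalties(k, grp.n, params)
        contrib[:, j] = s_vec * e * pen_k * pen_n
        gids.append(grp.group_id or f"group_{j + 1}")

    scores = contrib.sum(axis=1)
    ranks = rankdata(-scores, method="average")
    n_c = len(ranked)
    table = pd.DataFrame(
        {"score": scores, "rank": ranks, "rank_ratio": ranks / n_c},
        index=pd.Index(ranked, name="gene"),
    )
    contributions = pd.DataFrame(contrib, index=table.index, columns=gids)
    order = np.argsort(ranks, kind="stable")
    return RankingResult(
        table=table.iloc[order],
        contributions=contributions.iloc[order],
        groups=usable,
        unranked=unranked,
    )


def single_rank(candidates, de, S, net,
                params: ScoringParams | None = None) -> RankingResult:
    """Baseline ranking against individual DE genes.

    Every DE gene forms its own singleton group (n = 1, e = |log2 ratio|),
    scored and integrated exactly like GroupRank groups.
    """
    singletons = [
        GeneGroup(members=[g], group_id=f"single_{g}")
        for g in de.de_genes
    ]
    return rank_candidates(candidates, singletons, S, net, de, params)


def ranking_to_frame(result: RankingResult) -> pd.DataFrame:
    """Flat export: gene, score, rank, rank ratio, top group, contribution %."""
    rows = []
    for gene in result.table.index:
        gid, share = result.top_contributor(gene)
        rows.append((gene, result.score_of(gene), result.rank_of(gene),
                     float(result.table.at[gene, "rank_ratio"]),
                     gid, 100.0 * share))
    return pd.DataFrame(
        rows, columns=["gene", "score", "rank", "rank_ratio",
                       "top_group", "top_group_pct"],
    )
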