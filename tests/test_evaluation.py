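"""Rank ratios, ROC/AUC, threshold sweep, nulls and method comparison."""

import numpy as np
import pandas as pd
import pytest

import grouprank as gr
from grouprank.evaluation import DEFAULT_GRID, EvaluationError
from grouprank.scoring import RankingResult


def ranking_from_scores(scores: dict) -> RankingResult:
    """Build a RankingResult directly from a gene -> score mapping."""
    from scipy.stats import rankdata

    genes = list(scores)
    vals = np.array([scores[g] for g in genes], dtype=float)
    ranks = rankdata(-vals, method="average")
    table = pd.DataFrame(
        {"score": vals, "rank": ranks, "rank_ratio": ranks / len(genes)},
        index=pd.Index(genes, name="gene"),
    )
    order = np.argsort(ranks, kind="stable")
    contributions = pd.DataFrame({"group_1": vals}, index=table.index)
    return RankingResult(table=table.iloc[order],
                         contributions=contributions.iloc[order], groups=[])


def bruteforce_auc(ranking: RankingResult, known) -> float:
    """All-pairs comparison oracle: P(score_pos > score_neg) + 0.5 ties."""
    known = set(known)
    pos = ranking.table.loc[[g for g in ranking.table.index if g in known],
                            "score"].to_numpy()
    neg = ranking.table.loc[[g for g in ranking.table.index
                             if g not in known], "score"].to_numpy()
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


class TestRankRatio:
    def test_top_and_bottom_of_hundred(self):
        scores = {f"g{i}": 100.0 - i for i in range(100)}
        r = ranking_from_scores(scores)
        assert gr.rank_ratio(r, "g0") == pytest.approx(0.01)
        assert gr.rank_ratio(r, "g99") == pytest.approx(1.0)

    def test_tie_gets_average_rank_ratio(self):
        scores = {f"g{i}": 10.0 - i for i in range(10)}
        scores["g2"] = scores["g3"] = 7.5  # tie at positions 3-4
        r = ranking_from_scores(scores)
        assert gr.rank_ratio(r, "g2") == pytest.approx(0.35)

    def test_unranked_gene_raises(self):
        r = ranking_from_scores({"a": 1.0, "b": 0.5})
        with pytest.raises(EvaluationError, match="ghost"):
            gr.rank_ratio(r, "ghost")


class TestMeanRankRatio:
    def test_arithmetic_mean(self):
        scores = {f"g{i}": 10.0 - i for i in range(10)}
        r = ranking_from_scores(scores)
        assert gr.mean_rank_ratio(r, ["g0", "g2"]) == pytest.approx(
            (0.1 + 0.3) / 2)

    def test_all_last_gives_one(self):
        r = ranking_from_scores({"a": 0.0, "b": 0.0, "top": 5.0})
        assert gr.mean_rank_ratio(r, ["a", "b"]) == pytest.approx(
            (2.5 / 3 + 2.5 / 3) / 2)

    def test_no_rankable_known_gene_raises(self):
        r = ranking_from_scores({"a": 1.0})
        with pytest.raises(EvaluationError, match="no known gene"):
            gr.mean_rank_ratio(r, ["ghost"])

    def test_random_scores_mean_near_half(self):
        rng = np.random.default_rng(0)
        mrrs = []
        for _ in range(100):
            scores = {f"g{i}": rng.random() for i in range(50)}
            r = ranking_from_scores(scores)
            mrrs.append(gr.mean_rank_ratio(r, ["g0", "g1", "g2"]))
        assert np.mean(mrrs) == pytest.approx(0.5, abs=0.05)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {f"p{i}": 10.0 + i for i in range(3)}
        scores.update({f"n{i}": float(i) for i in range(5)})
        auc, roc = gr.roc_auc(ranking_from_scores(scores),
                              [f"p{i}" for i in range(3)])
        assert auc == 1.0
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_all_tied_is_half(self):
        scores = {f"g{i}": 1.0 for i in range(11)}
        auc, _ = gr.roc_auc(ranking_from_scores(scores), ["g5"])
        assert auc == pytest.approx(0.5)

    def test_no_negatives_raises(self):
        r = ranking_from_scores({"a": 1.0, "b": 2.0})
        with pytest.raises(EvaluationError):
            gr.roc_auc(r, ["a", "b"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = {f"g{i}": float(rng.choice([0.1, 0.5, rng.random()]))
                  for i in range(n)}
        known = [f"g{i}" for i in rng.choice(n, size=5, replace=False)]
        r = ranking_from_scores(scores)
        auc, _ = gr.roc_auc(r, known)
        assert auc == pytest.approx(bruteforce_auc(r, known), abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(100):
            scores = {f"g{i}": rng.random() for i in range(60)}
            auc, _ = gr.roc_auc(ranking_from_scores(scores),
                                ["g0", "g1", "g2"])
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)


class TestRocAucProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=4, max_size=40),
           st.integers(min_value=1, max_value=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_bounded_and_equals_oracle(self, raw_scores, n_pos):
        n_pos = min(n_pos, len(raw_scores) - 1)
        scores = {f"g{i}": s for i, s in enumerate(raw_scores)}
        known = [f"g{i}" for i in range(n_pos)]
        r = ranking_from_scores(scores)
        auc, _ = gr.roc_auc(r, known)
        assert 0.0 <= auc <= 1.0
        assert auc == pytest.approx(bruteforce_auc(r, known), abs=1e-12)


class TestThresholdSweep:
    def test_grid_has_101_points(self):
        assert len(DEFAULT_GRID) == 101
        assert DEFAULT_GRID[0] == 0.0 and DEFAULT_GRID[-1] == 1.0

    def test_sweep_on_planted_instance(self, default_instance):
        inst = default_instance
        de = gr.de_test(inst.expression)
        S = gr.kernel_for_network(inst.network)
        grid = np.round(np.arange(0, 1.01, 0.1), 2)
        sweep = gr.threshold_sweep(
            inst.expression, inst.network, S, de,
            inst.truth.disease_genes, d_grid=grid)
        assert len(sweep.table) == len(grid)
        assert (sweep.table["n_groups"].diff().dropna() <= 0).all()
        assert sweep.best_mrr <= sweep.table["mrr"].iloc[0] + 1e-12

    def test_tie_goes_to_smallest_d(self, default_instance):
        """With no DE structure the curve is flat and the optimum is d=0."""
        inst = gr.make_instance(seed=20, effect=0.0)
        de = gr.de_test(inst.expression)
        S = gr.kernel_for_network(inst.network)
        grid = np.round(np.arange(0, 1.01, 0.25), 2)
        sweep = gr.threshold_sweep(
            inst.expression, inst.network, S, de,
            inst.truth.disease_genes, d_grid=grid)
        if sweep.table["mrr"].nunique() == 1:
            assert sweep.best_d == 0.0


class TestRandomGroupNull:
    def test_seeded_null_is_bit_reproducible(self, default_instance,
                                             default_pipeline):
        inst = default_instance
        de, S, groups = default_pipeline
        kwargs = dict(n_resamples=25, seed=123)
        r1 = gr.random_group_null(groups, inst.network, S, de,
                                  inst.truth.disease_genes, **kwargs)
        r2 = gr.random_group_null(groups, inst.network, S, de,
                                  inst.truth.disease_genes, **kwargs)
        assert np.array_equal(r1.null_mrrs, r2.null_mrrs)
        assert r1.p_value == r2.p_value

    def test_add_one_p_value_convention(self, default_instance,
                                        default_pipeline):
        inst = default_instance
        de, S, groups = default_pipeline
        res = gr.random_group_null(groups, inst.network, S, de,
                                   inst.truth.disease_genes,
                                   n_resamples=50, seed=5)
        b = int((res.null_mrrs <= res.observed_mrr).sum())
        assert res.p_value == pytest.approx((b + 1) / 51)

    def test_oversized_group_rejected(self, default_instance,
                                      default_pipeline):
        inst = default_instance
        de, S, _ = default_pipeline
        giant = gr.GeneGroup(members=["x"] )
        giant.members = ["x"] * (inst.network.n_nodes + 1)
        with pytest.raises(EvaluationError, match="exceeds"):
            gr.random_group_null([giant], inst.network, S, de,
                                 inst.truth.disease_genes, n_resamples=2)

    def test_requires_groups(self, default_instance, default_pipeline):
        inst = default_instance
        de, S, _ = default_pipeline
        with pytest.raises(EvaluationError, match="grouping"):
            gr.random_group_null([], inst.network, S, de,
                                 inst.truth.disease_genes)


class TestCompareMethods:
    def test_identical_pairs_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            p = gr.compare_methods([1.0] * 6, [1.0] * 6)
        assert p == 1.0

    def test_consistent_direction_exact_p(self):
        rng = np.random.default_rng(2)
        b = rng.random(20)
        a = b - rng.uniform(0.01, 0.1, size=20)  # A beats B every time
        assert gr.compare_methods(a, b) == pytest.approx(2 * 2.0 ** -20,
                                                         rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EvaluationError, match=">= 5"):
            gr.compare_methods([1, 2], [2, 1])

    def test_type_one_error_calibrated_under_exchangeability(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if gr.compare_methods(a, b) < 0.05:
                rejections += 1
        rate = rejections / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestEvaluateReport:
    def test_report_fields_consistent(self, default_instance,
                                      default_pipeline):
        inst = default_instance
        de, S, groups = default_pipeline
        ranking = gr.rank_candidates(inst.network.nodes, groups, S,
                                     inst.network, de)
        report = gr.evaluate(ranking, inst.truth.disease_genes + ["GHOST"])
        assert report.excluded == ["GHOST"]
        assert 0 < report.mrr <= 1
        assert 0 <= report.auc <= 1
        assert len(report.per_gene) == len(inst.truth.disease_genes)
        assert report.mrr == pytest.approx(
            report.per_gene["rank_ratio"].mean())
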