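import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpxwalk import (
    GeneSet,
    NetworkLayer,
    RWRParams,
    make_folds,
    make_multiplex_from_layers,
    rank_metrics,
    rerank,
    run_cv,
)
from mpxwalk.errors import FoldError, MetricError, NoSeedsError


def geneset(n, prefix="s"):
    return GeneSet("gs", [f"{prefix}{i:02d}" for i in range(n)])


class TestFolds:
    def test_loo_makes_one_fold_per_gene(self):
        plan = make_folds(geneset(30), "loo")
        assert plan.K == 30 and len(plan.folds) == 30
        held = [h for _, hs in plan.folds for h in hs]
        assert sorted(held) == sorted(geneset(30).members)

    def test_kfold_sizes_differ_by_at_most_one(self):
        plan = make_folds(geneset(27), "kfold", K=5, rng_seed=1)
        sizes = sorted(len(h) for _, h in plan.folds)
        # 27 = 6 + 6 + 5 + 5 + 5: two folds take the remainder
        assert sizes == [5, 5, 5, 6, 6]
        assert max(sizes) - min(sizes) <= 1

    def test_kfold_partitions_gene_set(self):
        gs = geneset(13)
        plan = make_folds(gs, "kfold", K=4, rng_seed=2)
        held = [h for _, hs in plan.folds for h in hs]
        assert sorted(held) == sorted(gs.members)
        for train, held_f in plan.folds:
            assert set(train) | set(held_f) == set(gs.members)
            assert not set(train) & set(held_f)

    def test_singletons_train_on_one_gene(self):
        plan = make_folds(geneset(3), "singletons")
        for i, (train, held) in enumerate(plan.folds):
            assert len(train) == 1 and len(held) == 2
            assert train[0] not in held

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(FoldError):
            make_folds(geneset(3), "kfold", K=5)

    def test_tiny_gene_set_rejected(self):
        with pytest.raises(FoldError):
            make_folds(GeneSet("g", ["only"]), "loo")

    def test_seeded_shuffle_reproducible(self):
        a = make_folds(geneset(10), "kfold", K=3, rng_seed=9)
        b = make_folds(geneset(10), "kfold", K=3, rng_seed=9)
        assert a.folds == b.folds


class TestRankMetrics:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2, 0.1])
        pos = np.array([True, True, False, False, False])
        m = rank_metrics(scores, pos)
        assert m["AUROC"] == 1.0 and m["AUPRC"] == 1.0

    @pytest.mark.parametrize("j", [1, 3, 7, 10])
    def test_single_positive_closed_form(self, j):
        # one positive at rank j of n has AUROC (n - j) / (n - 1)
        n = 10
        scores = np.arange(n, 0, -1, dtype=float)
        pos = np.zeros(n, dtype=bool)
        pos[j - 1] = True
        m = rank_metrics(scores, pos)
        assert m["AUROC"] == pytest.approx((n - j) / (n - 1))

    def test_all_tied_scores_give_half(self):
        m = rank_metrics(np.ones(6), np.array([1, 0, 1, 0, 0, 0], dtype=bool))
        assert m["AUROC"] == 0.5

    def test_matches_sklearn_on_untied_scores(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.permutation(np.arange(50, dtype=float))
            pos = rng.random(50) < 0.2
            if not pos.any() or pos.all():
                continue
            m = rank_metrics(scores, pos)
            assert m["AUROC"] == pytest.approx(roc_auc_score(pos, scores))
            assert m["AUPRC"] == pytest.approx(
                average_precision_score(pos, scores)
            )

    def test_random_scores_have_null_auroc_half(self):
        rng = np.random.default_rng(12)
        reps = 3000
        vals = np.empty(reps)
        for i in range(reps):
            scores = rng.random(30)
            pos = np.zeros(30, dtype=bool)
            pos[:5] = True
            vals[i] = rank_metrics(scores, pos)["AUROC"]
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - 0.5) < 3 * se + 1e-3

    def test_precision_recall_at_k(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        pos = np.array([True, False, True, False, False])
        m = rank_metrics(scores, pos, k_grid=(2, 4))
        assert m["P@2"] == 0.5 and m["R@2"] == 0.5
        assert m["P@4"] == 0.5 and m["R@4"] == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            rank_metrics(np.arange(4.0), np.zeros(4, dtype=bool))


class TestRerank:
    def test_tie_groups_share_smallest_rank(self):
        out = rerank([1, 1, 1, 1, 1, 2])
        np.testing.assert_array_equal(out, [1, 1, 1, 1, 1, 6])

    def test_three_tie_groups(self):
        out = rerank([1] * 5 + [2] * 5 + [3] * 3)
        np.testing.assert_array_equal(out, [1] * 5 + [6] * 5 + [11] * 3)

    def test_strictly_increasing_is_identity(self):
        np.testing.assert_array_equal(rerank([1.5, 2.0, 7.0]), [1, 2, 3])

    def test_all_equal_all_one(self):
        np.testing.assert_array_equal(rerank([4, 4, 4]), [1, 1, 1])

    def test_monotone_in_meanrank(self):
        rng = np.random.default_rng(0)
        mr = rng.integers(1, 10, size=40).astype(float)
        rr = rerank(mr)
        order = np.argsort(mr)
        assert np.all(np.diff(rr[order]) >= 0)

    @given(
        st.lists(st.floats(min_value=1, max_value=1e4), min_size=1, max_size=60)
    )
    @settings(deadline=None, derandomize=True)
    def test_rerank_is_a_valid_competition_ranking(self, mr):
        mr = np.asarray(mr)
        rr = rerank(mr)
        assert rr.min() == 1
        for a in range(len(mr)):
            # competition rank = 1 + number of strictly better meanranks
            assert rr[a] == 1 + np.sum(mr < mr[a])


def modular_multiplex():
    """Gene-set clique in both layers; background is a sparse ring."""
    clique = [f"s{i:02d}" for i in range(6)]
    background = [f"b{i:02d}" for i in range(8)]
    clique_edges = [
        (a, b, 1.0) for i, a in enumerate(clique) for b in clique[i + 1:]
    ]
    ring = [
        (background[i], background[(i + 1) % len(background)], 1.0)
        for i in range(len(background))
    ]
    bridge = [(clique[0], background[0], 1.0)]
    layers = [
        NetworkLayer("l1", clique_edges + ring + bridge),
        NetworkLayer("l2", clique_edges + ring),
    ]
    return make_multiplex_from_layers(layers), GeneSet("clique", clique)


class TestRunCV:
    def test_separable_topology_ranks_held_out_first(self):
        mpx, gs = modular_multiplex()
        rep = run_cv(mpx, gs, "loo", params=RWRParams())
        held = rep.fullranks[rep.fullranks["held_out"]]
        assert (held["rank"] == 1).all()
        assert (rep.metrics["AUROC"] == 1.0).all()

    def test_kfold_report_reproducible(self):
        mpx, gs = modular_multiplex()
        a = run_cv(mpx, gs, "kfold", K=3, rng_seed=5)
        b = run_cv(mpx, gs, "kfold", K=3, rng_seed=5)
        pd.testing.assert_frame_equal(a.fullranks, b.fullranks)
        pd.testing.assert_frame_equal(a.meanranks, b.meanranks)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_absent_members_dropped_with_warning(self):
        mpx, gs = modular_multiplex()
        gs2 = GeneSet("g", gs.members + ["ghost"])
        with pytest.warns(UserWarning, match="ghost"):
            rep = run_cv(mpx, gs2, "loo")
        assert rep.K == len(gs.members)

    def test_too_few_present_members_rejected(self):
        mpx, _ = modular_multiplex()
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(NoSeedsError):
                run_cv(mpx, GeneSet("g", ["s00", "ghost1", "ghost2"]), "loo")

    def test_meanrank_spans_all_ranked_genes(self):
        mpx, gs = modular_multiplex()
        rep = run_cv(mpx, gs, "loo")
        # background genes are ranked in every fold and re-ranked too
        assert set(rep.meanranks["gene"]) == set(mpx.nodes)
        assert rep.meanranks["rerank"].min() == 1
        assert (rep.meanranks["meanrank"] >= 1).all()

    def test_held_out_once_per_gene_in_kfold(self):
        mpx, gs = modular_multiplex()
        rep = run_cv(mpx, gs, "kfold", K=3, rng_seed=1)
        held_counts = (
            rep.fullranks[rep.fullranks["held_out"]]
            .groupby("gene")
            .size()
        )
        assert (held_counts == 1).all()
        assert sorted(held_counts.index) == sorted(gs.members)
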