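import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualeb import (
    PredictionRule,
    SimConfig,
    cross_validate,
    fit_prediction_rule,
    predict_scores,
    rank_genes,
    roc_auc,
    select_top_genes,
    simulate_tissue_pair,
    topk_recovery,
)


class TestSelectTopGenes:
    def test_ordered_by_magnitude(self):
        idx = select_top_genes(np.array([0.1, -3.0, 2.0]), 2)
        assert list(idx) == [1, 2]

    def test_k_equals_n_is_a_permutation(self):
        delta = np.array([0.5, -0.1, 2.0, 1.0])
        assert sorted(select_top_genes(delta, 4)) == [0, 1, 2, 3]

    def test_tie_broken_by_input_order(self):
        assert list(select_top_genes(np.array([1.0, -1.0]), 1)) == [0]

    @pytest.mark.parametrize("k", [0, -1, 5])
    def test_invalid_k(self, k):
        with pytest.raises(ValueError, match="k must be"):
            select_top_genes(np.ones(4), k)


class TestPredictScores:
    def test_single_gene_score(self):
        rule = PredictionRule(
            selected_genes=["g"],
            coefficients=np.array([1.0]),
            center=np.array([0.0]),
            scale=np.array([1.0]),
        )
        scores = predict_scores(rule, np.array([[2.0]]), ["g"])
        assert scores[0] == pytest.approx(2.0)

    def test_cancellation_scores_zero(self):
        rule = PredictionRule(
            selected_genes=["a", "b"],
            coefficients=np.array([1.0, -1.0]),
            center=np.zeros(2),
            scale=np.ones(2),
        )
        scores = predict_scores(rule, np.array([[1.0], [1.0]]), ["a", "b"])
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_dot_product(self):
        rng = np.random.default_rng(30)
        genes = [f"g{i}" for i in range(10)]
        rule = PredictionRule(
            selected_genes=genes,
            coefficients=rng.standard_normal(10),
            center=rng.standard_normal(10),
            scale=np.abs(rng.standard_normal(10)) + 0.5,
        )
        X = rng.standard_normal((10, 6))
        scores = predict_scores(rule, X, genes)
        expected = [
            sum(
                rule.coefficients[i] * (X[i, j] - rule.center[i]) / rule.scale[i]
                for i in range(10)
            )
            for j in range(6)
        ]
        assert np.allclose(scores, expected, atol=1e-12)

    def test_missing_gene_rejected(self):
        rule = PredictionRule(
            selected_genes=["a"],
            coefficients=np.array([1.0]),
            center=np.zeros(1),
            scale=np.ones(1),
        )
        with pytest.raises(ValueError, match="missing selected gene"):
            predict_scores(rule, np.zeros((1, 2)), ["b"])


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, points = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(1.0)
        assert (0.0, 0.0) in points and (1.0, 1.0) in points

    def test_complete_ties_give_half(self):
        auc, _ = roc_auc(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert auc == pytest.approx(0.5)

    def test_printed_example(self):
        # concordant pairs: 3 of 4 case-control pairs
        auc, _ = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.zeros(4, dtype=int))

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(30)
        labels = np.zeros(30, dtype=int)
        labels[rng.choice(30, 12, replace=False)] = 1
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(31)
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestTopkRecovery:
    def test_truth_superset_counts_k(self):
        ranking = ["a", "b", "c", "d"]
        assert topk_recovery(ranking, {"a", "b", "c", "d", "e"}, 3)["count"] == 3

    def test_disjoint_truth_counts_zero(self):
        assert topk_recovery(["a", "b"], {"x"}, 2)["count"] == 0

    def test_planted_positions(self):
        ranking = [f"g{i}" for i in range(10)]
        truth = {"g1", "g4", "g8"}  # ranks 2, 5, 9
        assert topk_recovery(ranking, truth, 5)["count"] == 2

    def test_tissue_attribution(self):
        ranking = ["a", "b", "c"]
        out = topk_recovery(
            ranking, {"a", "b"}, 2, truth_first={"a"}, truth_second={"b", "c"}
        )
        assert out == {"count": 2, "first": 1, "second": 1}

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must be"):
            topk_recovery(["a"], {"a"}, 2)


class TestCrossValidate:
    def test_huge_effects_are_perfectly_classified(self):
        cfg = SimConfig(
            n_genes=500, n_de=20, effect_first=5.0, effect_second=5.0,
            frac_de_first_only=0.0, frac_de_second_only=0.0, frac_de_both=1.0,
            seed=40,
        )
        pair, _ = simulate_tissue_pair(cfg)
        res = cross_validate(pair.first, method="single", k=20, n_repeats=5, seed=1)
        assert res.mean_error == pytest.approx(0.0)
        assert res.auc == pytest.approx(1.0)

    def test_same_seed_is_bit_reproducible(self, small_pair):
        pair = small_pair[0]
        r1 = cross_validate(pair, method="weighted_z", k=30, n_repeats=3, seed=9,
                            n_permutations=5)
        r2 = cross_validate(pair, method="weighted_z", k=30, n_repeats=3, seed=9,
                            n_permutations=5)
        assert r1.per_repeat_errors == r2.per_repeat_errors
        assert r1.auc == r2.auc

    def test_insufficient_samples_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="at least"):
            cross_validate(toy_dataset, method="single", k=1, n_repeats=1, seed=0)

    def test_wrong_input_type_rejected(self, small_pair):
        with pytest.raises(TypeError, match="PairedDatasets"):
            cross_validate(small_pair[0].first, method="weighted_z", k=10)

    def test_unknown_method_rejected(self, small_pair):
        with pytest.raises(ValueError, match="unknown method"):
            cross_validate(small_pair[0], method="fisher", k=10)

    def test_result_fields_consistent(self, small_pair):
        pair = small_pair[0]
        res = cross_validate(pair.first, method="single", k=30, n_repeats=4, seed=2)
        assert len(res.per_repeat_errors) == 4
        assert res.mean_error == pytest.approx(np.mean(res.per_repeat_errors))
        assert res.sd_error == pytest.approx(np.std(res.per_repeat_errors, ddof=1))
        assert 0.0 <= res.auc <= 1.0

    def test_paper_mode_uses_full_sample_weights(self, small_pair):
        pair = small_pair[0]
        res = cross_validate(
            pair, method="weighted_gene", k=30, n_repeats=2, seed=3,
            paper_mode=True, n_permutations=4,
        )
        assert len(res.per_repeat_errors) == 2


class TestRankGenes:
    def test_ordered_by_shrunken_magnitude(self, small_pair):
        frame = rank_genes(small_pair[0].first, method="single")
        mags = frame["delta_hat"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)

    def test_gene_reordering_invariance(self, small_pair):
        ds = small_pair[0].first
        rng = np.random.default_rng(41)
        perm = rng.permutation(ds.n_genes)
        shuffled = ds.subset_genes(perm)
        a = rank_genes(ds, method="single")
        b = rank_genes(shuffled, method="single")
        assert set(a["gene_id"][:50]) == set(b["gene_id"][:50])


def test_fit_prediction_rule_round_trip(small_pair):
    ds = small_pair[0].first
    rule = fit_prediction_rule(ds, k=25)
    scores = predict_scores(rule, ds.X, ds.gene_ids)
    assert scores.shape == (ds.n_samples,)
    # training scores should separate classes better than chance
    auc, _ = roc_auc(scores, ds.y)
    assert auc > 0.5
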