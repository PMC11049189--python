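import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualeb import (
    ExpressionDataset,
    combine_weighted_genes,
    combine_weighted_z,
    estimate_rho,
    gene_weights,
    per_gene_logistic_pvalues,
    weighted_z_sd,
    z_weights,
)


def _dataset(X, y):
    X = np.asarray(X, dtype=float)
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(X.shape[0])],
        sample_ids=[f"s{j}" for j in range(X.shape[1])],
        X=X,
        y=np.asarray(y),
    )


class TestLogisticPvalues:
    def test_uninformative_gene_gives_p_one(self):
        # identical values in both classes carry no label information
        X = np.array([[3.0, 3.0, 3.0, 3.0, 3.0, 3.0]])
        p = per_gene_logistic_pvalues(_dataset(X, [0, 0, 0, 1, 1, 1]))
        assert p[0] == pytest.approx(1.0)

    def test_perfect_separation_hits_clip_floor(self, caplog):
        X = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        with caplog.at_level("WARNING"):
            p = per_gene_logistic_pvalues(_dataset(X, [0, 0, 0, 1, 1, 1]))
        assert p[0] == 1e-300
        assert "separation" in caplog.text

    def test_agrees_with_statsmodels_logit(self):
        """Independent maximum-likelihood oracle for the LRT p-value."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        n = 200
        x = rng.standard_normal(n)
        eta = 0.3 + 1.0 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        p_ours = per_gene_logistic_pvalues(_dataset(x[None, :], y))[0]

        res = sm.Logit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        from scipy import stats as sps

        lrt = 2 * (res.llf - res.llnull)
        p_oracle = sps.chi2.sf(lrt, 1)
        assert p_ours == pytest.approx(p_oracle, rel=1e-3)

    def test_vectorization_matches_per_gene_loop(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 16))
        y = np.array([0] * 8 + [1] * 8)
        batch = per_gene_logistic_pvalues(_dataset(X, y))
        single = np.array(
            [per_gene_logistic_pvalues(_dataset(X[i : i + 1], y))[0] for i in range(20)]
        )
        assert np.allclose(batch, single, rtol=1e-8)


class TestGeneWeights:
    def test_direct_evaluation(self):
        # -log(0.01) / (-log(0.01) - log(0.1)) = 2/3
        w = gene_weights(np.array([0.01]), np.array([0.1]))
        assert w[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_equal_evidence_gives_half(self):
        assert gene_weights(np.array([0.2]), np.array([0.2]))[0] == pytest.approx(0.5)
        assert gene_weights(np.array([1.0]), np.array([1.0]))[0] == pytest.approx(0.5)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="p_first"):
            gene_weights(np.array([0.0]), np.array([0.5]))

    @settings(deadline=None, max_examples=50)
    @given(
        p1=st.floats(1e-10, 1.0, exclude_min=False),
        p2=st.floats(1e-10, 1.0),
    )
    def test_swap_symmetry_and_range(self, p1, p2):
        w = gene_weights(np.array([p1]), np.array([p2]))[0]
        w_swapped = gene_weights(np.array([p2]), np.array([p1]))[0]
        assert 0.0 <= w <= 1.0
        assert w + w_swapped == pytest.approx(1.0, abs=1e-9)


class TestCombineWeightedGenes:
    def test_extreme_weights_reproduce_inputs(self, small_pair):
        pair = small_pair[0]
        n = len(pair.gene_ids)
        assert np.allclose(combine_weighted_genes(pair, np.ones(n)).X, pair.first.X)
        assert np.allclose(combine_weighted_genes(pair, np.zeros(n)).X, pair.second.X)

    def test_direct_evaluation(self, toy_dataset):
        import dataclasses

        from dualeb import PairedDatasets

        first = dataclasses.replace(toy_dataset, X=np.full((3, 4), 4.0))
        second = dataclasses.replace(toy_dataset, X=np.full((3, 4), 8.0))
        pair = PairedDatasets(first, second)
        out = combine_weighted_genes(pair, np.full(3, 0.25))
        assert np.allclose(out.X, 7.0)

    def test_convexity(self, small_pair):
        pair = small_pair[0]
        rng = np.random.default_rng(12)
        w = rng.random(len(pair.gene_ids))
        out = combine_weighted_genes(pair, w)
        lo = np.minimum(pair.first.X, pair.second.X)
        hi = np.maximum(pair.first.X, pair.second.X)
        assert np.all(out.X >= lo - 1e-12) and np.all(out.X <= hi + 1e-12)

    def test_invalid_weights_rejected(self, small_pair):
        pair = small_pair[0]
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            combine_weighted_genes(pair, np.full(len(pair.gene_ids), 1.5))


class TestZWeights:
    def test_direct_evaluation(self):
        zw = z_weights(np.array([2.0]), np.array([-1.0]))
        assert zw[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_degenerate_and_symmetric_cases(self):
        assert z_weights(np.array([0.0]), np.array([0.0]))[0] == 0.5
        assert z_weights(np.array([1.3]), np.array([-1.3]))[0] == pytest.approx(0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            z_weights(np.array([np.inf]), np.array([1.0]))

    @settings(deadline=None, max_examples=50)
    @given(z1=st.floats(-50, 50), z2=st.floats(-50, 50))
    def test_swap_symmetry(self, z1, z2):
        a = z_weights(np.array([z1]), np.array([z2]))[0]
        b = z_weights(np.array([z2]), np.array([z1]))[0]
        assert a + b == pytest.approx(1.0, abs=1e-9)


class TestCombineWeightedZ:
    def test_extreme_weights(self):
        z1, z2 = np.array([2.0, -3.0]), np.array([0.5, 1.0])
        assert np.allclose(combine_weighted_z(z1, z2, np.ones(2)), z1)
        assert np.allclose(combine_weighted_z(z1, z2, np.zeros(2)), z2)

    def test_direct_evaluation(self):
        out = combine_weighted_z(
            np.array([2.0]), np.array([-1.0]), np.array([2.0 / 3.0])
        )
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            combine_weighted_z(np.zeros(3), np.zeros(2), np.zeros(3))


class TestRho:
    def test_identical_vectors_give_one(self):
        z = np.random.default_rng(13).standard_normal(100)
        assert estimate_rho(z, z) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(14)
        assert abs(estimate_rho(rng.standard_normal(10_000), rng.standard_normal(10_000))) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_rho(np.arange(5.0), np.ones(5))


class TestWeightedZSd:
    def test_rho_one_gives_unit_sd_for_any_weight(self):
        zw = np.linspace(0.0, 1.0, 11)
        assert np.allclose(weighted_z_sd(zw, 1.0), 1.0, atol=1e-12)

    def test_direct_evaluation(self):
        assert weighted_z_sd(np.array([0.5]), 0.0)[0] == pytest.approx(
            np.sqrt(0.5), abs=1e-12
        )

    def test_perfect_anticorrelation_cancels(self):
        assert weighted_z_sd(np.array([0.5]), -1.0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            weighted_z_sd(np.array([0.5]), 1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            weighted_z_sd(np.array([-0.1]), 0.0)
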