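"""Scikit-learn style classifiers built on the empirical-Bayes rule.

All three estimators follow the sklearn contract: hyperparameters in
``__init__``, ``fit(X, y)`` with ``X`` of shape (n_samples, n_features),
fitted attributes with a trailing underscore, ``decision_function`` /
``predict``, and compatibility with ``clone`` and pipelines.

* :class:`EmpiricalBayesClassifier` — one expression matrix; ranks genes
  by the Tweedie-shrunken score ``delta_hat`` and classifies a sample as
  diseased when ``sum_{i in I} delta_hat_i * W_i > 0`` over the top-k
  gene set I, with W the training-standardized expression.
* :class:`WeightedGeneClassifier` — two tissues side by side
  (``X = [X_first | X_second]``); convexly combines the tissues per gene
  with -log p-value weights, then applies the single-matrix rule.
* :class:`WeightedZClassifier` — combines the two tissues' normal scores
  with relative-|Z| weights, shrinks the combined score, and applies the
  resulting gene set and coefficients to each tissue separately.

A sample is scored positive (disease) only when its score is strictly
above zero; a score of exactly zero falls to the normal class.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import eb, integration
from .dataset import ExpressionDataset, PairedDatasets


def _matrix_group_z(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t -> z normal scores for a genes x samples matrix and label vector,
    without constructing a dataset (used inside permutation loops)."""
    n1 = int((y == 0).sum())
    n2 = int((y == 1).sum())
    X0, X1 = X[:, y == 0], X[:, y == 1]
    pooled = np.sqrt(
        ((n1 - 1) * X0.var(axis=1, ddof=1) + (n2 - 1) * X1.var(axis=1, ddof=1))
        / (n1 + n2 - 2)
    )
    d0 = np.sqrt(n1 * n2 / (n1 + n2))
    t = d0 * (X1.mean(axis=1) - X0.mean(axis=1)) / pooled
    return eb.t_to_z(t, n1 + n2 - 2)


def _null_quantile_map(null_pool: np.ndarray) -> callable:
    """Monotone map sending the permutation-null distribution of a
    statistic to standard normal scores.

    Built by piecewise-linear interpolation between the pooled null order
    statistics and the matching normal quantiles; outside the pooled range
    the boundary segment is continued linearly, so very strong observed
    statistics keep distinct (extrapolated) scores instead of saturating.
    """
    vals = np.sort(np.asarray(null_pool, dtype=float))
    M = vals.size
    probs = (np.arange(M) + 0.5) / M
    zq = sps.norm.ppf(probs)
    # thin to a manageable monotone grid; keep exact extremes
    if M > 4001:
        idx = np.unique(np.concatenate([
            np.linspace(0, M - 1, 4001).astype(int), [0, M - 1]
        ]))
        vals, zq = vals[idx], zq[idx]
    # collapse exact ties to keep interpolation well-defined
    vals, keep = np.unique(vals, return_index=True)
    zq = zq[keep]
    lo_slope = (zq[1] - zq[0]) / max(vals[1] - vals[0], 1e-12)
    hi_slope = (zq[-1] - zq[-2]) / max(vals[-1] - vals[-2], 1e-12)

    def transform(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = np.interp(v, vals, zq)
        below = v < vals[0]
        above = v > vals[-1]
        out = np.where(below, zq[0] + lo_slope * (v - vals[0]), out)
        out = np.where(above, zq[-1] + hi_slope * (v - vals[-1]), out)
        return out

    return transform


def _as_dataset(X: np.ndarray, y: np.ndarray, tissue: str = "") -> ExpressionDataset:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(X.shape[1])],
        sample_ids=[f"s{j}" for j in range(X.shape[0])],
        X=X.T,
        y=y,
        tissue=tissue,
    )


def _validate_xy(est, X, y=None, reset=True):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n_samples, n_features) array")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if reset:
        est.n_features_in_ = X.shape[1]
    elif X.shape[1] != est.n_features_in_:
        raise ValueError(
            f"X has {X.shape[1]} features, expected {est.n_features_in_}"
        )
    if y is None:
        return X
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of samples")
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all() or classes.size != 2:
        raise ValueError("y must contain both classes, coded 0 (normal) and 1 (disease)")
    return X, y.astype(int)


class EmpiricalBayesClassifier(ClassifierMixin, BaseEstimator):
    """Tweedie-shrunken top-k gene sign classifier for one expression matrix.

    Parameters
    ----------
    k : int, default=100
        Number of genes (largest ``|delta_hat|``) entering the rule.
    n_bins, spline_df : int
        Histogram bins and spline degrees of freedom of the Lindsey
        marginal-density fit.
    s2_mode : {"unit", "central"}
        Variance plugged into Tweedie's formula; "unit" uses 1.0,
        "central" a robust interquartile estimate of the null variance.

    Attributes
    ----------
    delta_hat_ : ndarray of shape (n_features,)
        Empirical-Bayes effect estimate per gene.
    selected_ : ndarray of shape (k,)
        Column indices of the selected genes, by decreasing ``|delta_hat|``.
    coef_ : ndarray of shape (k,)
        ``delta_hat`` of the selected genes.
    """

    def __init__(self, k: int = 100, n_bins: int = 120, spline_df: int = 7,
                 s2_mode: str = "unit"):
        self.k = k
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.s2_mode = s2_mode

    def fit(self, X, y):
        X, y = _validate_xy(self, X, y)
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}] (got {self.k})")
        ds = _as_dataset(X, y)
        ds.require_class_counts(2)
        stats_ = eb.compute_group_stats(ds)
        self.stats_ = stats_
        self._finish_fit(stats_.z, stats_)
        return self

    def _finish_fit(self, z_for_shrink, stats_):
        """Density fit, shrinkage and top-k selection shared by the
        weighted variants (which supply their own shrinkage input)."""
        density = eb.fit_log_density(z_for_shrink, self.n_bins, self.spline_df)
        s2 = eb.estimate_s2(z_for_shrink, self.s2_mode)
        delta = eb.tweedie_shrink(z_for_shrink, density, s2)

        self.classes_ = np.array([0, 1])
        self.density_ = density
        self.s2_ = s2
        self.delta_hat_ = delta
        self.eb_fit_ = eb.EBFit(density=density, s2=s2, delta_hat=delta, z=z_for_shrink)
        order = np.argsort(-np.abs(delta), kind="stable")
        self.ranking_ = order
        self.selected_ = order[: self.k]
        self.coef_ = delta[self.selected_]
        self.center_ = 0.5 * (stats_.mean0 + stats_.mean1)[self.selected_]
        self.scale_ = stats_.pooled_sd[self.selected_]

    def decision_function(self, X):
        check_is_fitted(self, "delta_hat_")
        X = _validate_xy(self, X, reset=False)
        W = (X[:, self.selected_] - self.center_) / self.scale_
        return W @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class WeightedGeneClassifier(ClassifierMixin, BaseEstimator):
    """Two-tissue classifier on -log p-value weighted gene combinations.

    ``X`` holds the two tissues side by side, first all genes of the first
    tissue then the same genes of the second: shape (n_samples, 2 * N).
    Per-gene logistic-regression p-values from each tissue give the weight
    ``w_i`` (relative -log p), the tissues are combined as
    ``X*_i = w_i X_i,first + (1 - w_i) X_i,second``, and the single-matrix
    empirical-Bayes rule is fitted to the combination.

    Because the weight leans toward the tissue where a gene happens to
    look more associated, the combined statistic's null distribution is
    wider and shorter-tailed than N(0, 1) even for pure-noise genes. With
    ``null_calibration=True`` (default) the combined z scores are mapped
    through their label-permutation null onto exact standard-normal
    scores before shrinkage, restoring the ``z ~ N(delta, 1)`` working
    model; the map is monotone, so the raw ranking is preserved.

    ``precomputed_weights`` bypasses the training-fold p-values with a
    fixed per-gene weight vector (used to reproduce protocols that derive
    weights from the full sample).
    """

    def __init__(self, k: int = 100, n_bins: int = 120, spline_df: int = 7,
                 s2_mode: str = "unit", precomputed_weights=None,
                 null_calibration: bool = True, n_permutations: int = 20,
                 random_state: int = 0):
        self.k = k
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.s2_mode = s2_mode
        self.precomputed_weights = precomputed_weights
        self.null_calibration = null_calibration
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _split(self, X):
        if X.shape[1] % 2:
            raise ValueError("X must stack two equal-width tissue blocks")
        n = X.shape[1] // 2
        return X[:, :n], X[:, n:]

    def _weights_for(self, X1, X2, Y):
        """Per-gene weights for one (possibly permuted) label assignment;
        X1/X2 are genes x samples, Y is (n,) or (B, n) for a batch."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        B = Y.shape[0]
        G = X1.shape[0]
        Xb1 = np.tile(X1, (B, 1))
        Xb2 = np.tile(X2, (B, 1))
        Yb = np.repeat(Y, G, axis=0)
        p1 = integration.logistic_lrt_pvalues(Xb1, Yb, warn=(B == 1))
        p2 = integration.logistic_lrt_pvalues(Xb2, Yb, warn=(B == 1))
        w = integration.gene_weights(p1, p2)
        return (w.reshape(B, G), p1.reshape(B, G), p2.reshape(B, G))

    def fit(self, X, y):
        X, y = _validate_xy(self, X, y)
        X1, X2 = self._split(X)
        X1g, X2g = X1.T, X2.T  # genes x samples
        if self.precomputed_weights is not None:
            w = np.asarray(self.precomputed_weights, dtype=float)
            if w.shape != (X1.shape[1],):
                raise ValueError("precomputed_weights must have one entry per gene")
            p1 = p2 = None
        else:
            wb, p1b, p2b = self._weights_for(X1g, X2g, y)
            w, p1, p2 = wb[0], p1b[0], p2b[0]
        self.weights_ = w
        self.p_first_ = p1
        self.p_second_ = p2
        self.gene_weights_ = integration.GeneWeights(
            gene_ids=[f"g{i}" for i in range(X1.shape[1])],
            method="weighted_gene", w=w, p_first=p1, p_second=p2,
        )
        X_star = w * X1 + (1.0 - w) * X2
        ds = _as_dataset(X_star, y)
        ds.require_class_counts(2)
        stats_ = eb.compute_group_stats(ds)
        z_obs = stats_.z

        if self.null_calibration:
            rng = np.random.default_rng(self.random_state)
            Y_perm = np.array([rng.permutation(y) for _ in range(self.n_permutations)])
            w_perm, _, _ = self._weights_for(X1g, X2g, Y_perm)
            pool = np.concatenate([
                _matrix_group_z(
                    wp[:, None] * X1g + (1.0 - wp)[:, None] * X2g, yp
                )
                for wp, yp in zip(w_perm, Y_perm)
            ])
            self.calibration_ = _null_quantile_map(pool)
            z_for_shrink = self.calibration_(z_obs)
        else:
            self.calibration_ = None
            z_for_shrink = z_obs

        self.stats_ = stats_
        self.z_calibrated_ = z_for_shrink
        self.n_features_in_ = X.shape[1]
        if not 1 <= self.k <= X1.shape[1]:
            raise ValueError(f"k must be in [1, {X1.shape[1]}] (got {self.k})")
        EmpiricalBayesClassifier._finish_fit(self, z_for_shrink, stats_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = _validate_xy(self, X, reset=False)
        X1, X2 = self._split(X)
        X_star = self.weights_ * X1 + (1.0 - self.weights_) * X2
        W = (X_star[:, self.selected_] - self.center_) / self.scale_
        return W @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class WeightedZClassifier(ClassifierMixin, BaseEstimator):
    """Two-tissue classifier on relative-|Z| weighted normal scores.

    ``X`` stacks the two tissues exactly as in
    :class:`WeightedGeneClassifier`. Each tissue's normal scores are
    combined per gene as ``Z^w = zw Z_first + (1 - zw) Z_second`` with
    ``zw = |Z_first| / (|Z_first| + |Z_second|)``; the combined score is
    shrunk by Tweedie's formula and the top-k genes by ``|delta_hat|``
    define the rule. Because no combined expression matrix exists, the
    rule is applied to each tissue's standardized expression separately;
    ``decision_function`` returns the average of the two tissue scores and
    ``decision_function_per_tissue`` exposes both.

    ``standardize_combined=True`` (default) divides ``Z^w`` by its
    theoretical SD ``s_{Z^w}(zw, rho)`` before shrinkage; the SD is always
    computed and stored in ``sd_combined_`` as a diagnostic. Because the
    weight leans toward the larger score, even the standardized combined
    statistic is not null-N(0, 1); ``null_calibration=True`` (default)
    maps it through its label-permutation null onto exact standard-normal
    scores before shrinkage (a monotone map, so the raw ranking is
    preserved).
    """

    def __init__(self, k: int = 100, n_bins: int = 120, spline_df: int = 7,
                 s2_mode: str = "unit", standardize_combined: bool = True,
                 precomputed_weights=None, null_calibration: bool = True,
                 n_permutations: int = 20, random_state: int = 0):
        self.k = k
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.s2_mode = s2_mode
        self.standardize_combined = standardize_combined
        self.precomputed_weights = precomputed_weights
        self.null_calibration = null_calibration
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _split(self, X):
        if X.shape[1] % 2:
            raise ValueError("X must stack two equal-width tissue blocks")
        n = X.shape[1] // 2
        return X[:, :n], X[:, n:]

    def _combined_statistic(self, z1, z2, rho, zw=None):
        """The (optionally standardized) weighted score as a pure function
        of the two z vectors; rho is held fixed so observed and
        permutation-null values are the same statistic."""
        if zw is None:
            zw = integration.z_weights(z1, z2)
        z_comb = integration.combine_weighted_z(z1, z2, zw)
        sd = integration.weighted_z_sd(zw, rho)
        v = z_comb / sd if self.standardize_combined else z_comb
        return v, z_comb, zw, sd

    def fit(self, X, y):
        X, y = _validate_xy(self, X, y)
        X1, X2 = self._split(X)
        ds1 = _as_dataset(X1, y)
        ds2 = _as_dataset(X2, y)
        stats1 = eb.compute_group_stats(ds1)
        stats2 = eb.compute_group_stats(ds2)
        rho = integration.estimate_rho(stats1.z, stats2.z)
        zw_fixed = None
        if self.precomputed_weights is not None:
            zw_fixed = np.asarray(self.precomputed_weights, dtype=float)
            if zw_fixed.shape != (X1.shape[1],):
                raise ValueError("precomputed_weights must have one entry per gene")
        v_obs, z_comb, zw, sd_comb = self._combined_statistic(
            stats1.z, stats2.z, rho, zw_fixed
        )

        if self.null_calibration:
            rng = np.random.default_rng(self.random_state)
            X1g, X2g = X1.T, X2.T
            pool = []
            for _ in range(self.n_permutations):
                yp = rng.permutation(y)
                z1p = _matrix_group_z(X1g, yp)
                z2p = _matrix_group_z(X2g, yp)
                pool.append(self._combined_statistic(z1p, z2p, rho, zw_fixed)[0])
            self.calibration_ = _null_quantile_map(np.concatenate(pool))
            z_for_shrink = self.calibration_(v_obs)
        else:
            self.calibration_ = None
            z_for_shrink = v_obs

        if not 1 <= self.k <= X1.shape[1]:
            raise ValueError(f"k must be in [1, {X1.shape[1]}] (got {self.k})")
        self.stats_first_ = stats1
        self.stats_second_ = stats2
        self.z_weights_ = zw
        self.z_combined_ = z_comb
        self.rho_ = rho
        self.sd_combined_ = sd_comb
        self.z_calibrated_ = z_for_shrink
        self.gene_weights_ = integration.GeneWeights(
            gene_ids=[f"g{i}" for i in range(X1.shape[1])],
            method="weighted_z", w=zw, z_first=stats1.z, z_second=stats2.z,
            rho=rho, z_combined=z_comb, sd_combined=sd_comb,
        )

        density = eb.fit_log_density(z_for_shrink, self.n_bins, self.spline_df)
        s2 = eb.estimate_s2(z_for_shrink, self.s2_mode)
        delta = eb.tweedie_shrink(z_for_shrink, density, s2)
        self.classes_ = np.array([0, 1])
        self.density_ = density
        self.s2_ = s2
        self.delta_hat_ = delta
        self.eb_fit_ = eb.EBFit(density=density, s2=s2, delta_hat=delta, z=z_for_shrink)
        order = np.argsort(-np.abs(delta), kind="stable")
        self.ranking_ = order
        self.selected_ = order[: self.k]
        self.coef_ = delta[self.selected_]
        return self

    def decision_function_per_tissue(self, X):
        check_is_fitted(self, "delta_hat_")
        X = _validate_xy(self, X, reset=False)
        X1, X2 = self._split(X)
        scores = []
        for Xt, st in ((X1, self.stats_first_), (X2, self.stats_second_)):
            center = 0.5 * (st.mean0 + st.mean1)[self.selected_]
            scale = st.pooled_sd[self.selected_]
            W = (Xt[:, self.selected_] - center) / scale
            scores.append(W @ self.coef_)
        return scores[0], scores[1]

    def decision_function(self, X):
        s1, s2 = self.decision_function_per_tissue(X)
        return 0.5 * (s1 + s2)

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def predict_per_tissue(self, X):
        s1, s2 = self.decision_function_per_tissue(X)
        return (s1 > 0).astype(int), (s2 > 0).astype(int)


def paired_design_matrix(pair: PairedDatasets) -> np.ndarray:
    """Stack a gene pair into the (n_samples, 2 * N) layout the two-tissue
    classifiers consume: first-tissue genes, then second-tissue genes."""
    return np.hstack([pair.first.X.T, pair.second.X.T])
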