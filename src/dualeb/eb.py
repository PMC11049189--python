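"""Per-gene two-sample statistics and Tweedie's-formula shrinkage.

The pipeline implemented here turns a two-group expression matrix into
empirical-Bayes effect estimates:

1. per-gene two-sample t statistics,
   ``t_i = d0 * (mean_disease - mean_normal) / s_i`` with the pooled SD
   ``s_i`` and the balanced-design scale ``d0 = sqrt(n1*n2/(n1+n2))``;
2. a quantile map to normal scores, ``z_i = Phi^{-1}(F_t(t_i; n-2))``,
   so that approximately ``z_i ~ N(delta_i, 1)``;
3. a nonparametric estimate of the marginal log-density ``lf(z)`` of the
   z scores by Lindsey's method (Poisson regression of histogram bin
   counts on a smooth spline basis);
4. Tweedie's formula ``delta_hat = z + s2 * lf'(z)``, the posterior mean
   of the effect given z, which shrinks the bulk of null z scores toward
   zero while retaining genuine signal in the tails.

Only the marginal density of z is estimated; no prior for the effects is
ever specified, which is what makes the estimator empirical-Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import interpolate, stats

from .dataset import ExpressionDataset

__all__ = [
    "GroupStats",
    "EBFit",
    "LindseyDensity",
    "compute_group_stats",
    "t_to_z",
    "z_to_t",
    "fit_log_density",
    "tweedie_shrink",
    "standardize_genes",
    "estimate_s2",
]

# F_t values are clipped to this band before the normal quantile map so z
# stays finite even for extreme t.
_P_CLIP = 1e-12


@dataclass
class GroupStats:
    """Per-gene class means, pooled SDs and (t, z) statistics."""

    gene_ids: list[str]
    mean0: np.ndarray  # normal-class mean per gene
    mean1: np.ndarray  # disease-class mean per gene
    pooled_sd: np.ndarray
    d0: float
    t: np.ndarray
    df: int
    z: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean0": self.mean0,
                "mean1": self.mean1,
                "pooled_sd": self.pooled_sd,
                "t": self.t,
                "z": self.z,
            }
        )


def compute_group_stats(dataset: ExpressionDataset) -> GroupStats:
    """Two-sample statistics for every gene of a labelled dataset.

    Raises if any gene has zero pooled variance (a constant gene cannot be
    standardized and would produce an infinite t).
    """
    dataset.require_class_counts(2)
    y = dataset.y
    n1, n2 = dataset.n1, dataset.n2
    n = n1 + n2
    X0 = dataset.X[:, y == 0]
    X1 = dataset.X[:, y == 1]
    mean0 = X0.mean(axis=1)
    mean1 = X1.mean(axis=1)
    var0 = X0.var(axis=1, ddof=1)
    var1 = X1.var(axis=1, ddof=1)
    pooled_sd = np.sqrt(((n1 - 1) * var0 + (n2 - 1) * var1) / (n - 2))
    if (pooled_sd <= 0).any():
        bad = [dataset.gene_ids[i] for i in np.flatnonzero(pooled_sd <= 0)[:5]]
        raise ValueError(f"zero pooled variance for gene(s) {bad}; clean the data first")
    d0 = float(np.sqrt(n1 * n2 / n))
    t = d0 * (mean1 - mean0) / pooled_sd
    df = n - 2
    z = t_to_z(t, df)
    return GroupStats(
        gene_ids=list(dataset.gene_ids),
        mean0=mean0,
        mean1=mean1,
        pooled_sd=pooled_sd,
        d0=d0,
        t=t,
        df=df,
        z=z,
    )


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to normal scores: ``z = Phi^{-1}(F_t(t; df))``.

    Strictly increasing in t; tail probabilities are clipped to
    ``[1e-12, 1 - 1e-12]`` so the result is always finite.
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not np.isfinite(t).all():
        raise ValueError("t statistics must be finite")
    p = stats.t.cdf(t, df)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return stats.norm.ppf(p)


def z_to_t(z: np.ndarray, df: int) -> np.ndarray:
    """Inverse of :func:`t_to_z` on the non-clipped range."""
    return stats.t.ppf(stats.norm.cdf(np.asarray(z, dtype=float)), df)


class LindseyDensity:
    """Smooth estimate of the log marginal density of z by Lindsey's method.

    The z scores are binned into ``n_bins`` equal-width bins spanning the
    data range padded by 10% on each side, and the bin counts are fitted by
    a Poisson GLM on a cubic B-spline basis of the bin midpoints with
    ``spline_df`` basis columns. The fitted linear predictor, normalized so
    the implied density integrates to one, is the log-density ``lf(z)``;
    its derivative ``lf'(z)`` is evaluated analytically from the spline
    coefficients.

    Outside the fitted range the log-density is continued linearly using
    the boundary derivative, up to half the data range beyond each edge;
    points farther out raise an error.
    """

    def __init__(self, n_bins: int = 120, spline_df: int = 7):
        if n_bins < 10:
            raise ValueError("n_bins must be at least 10")
        if spline_df < 4:
            raise ValueError("spline_df must be at least 4 (cubic basis)")
        self.n_bins = n_bins
        self.spline_df = spline_df

    # -- fitting ---------------------------------------------------------
    def fit(self, z: np.ndarray) -> "LindseyDensity":
        z = np.asarray(z, dtype=float)
        if z.size < 200:
            raise ValueError(
                f"need at least 200 z values for a reliable density fit (got {z.size})"
            )
        zmin, zmax = z.min(), z.max()
        rng = zmax - zmin
        if rng <= 0:
            raise ValueError("z values are all equal; density estimate undefined")
        lo, hi = zmin - 0.1 * rng, zmax + 0.1 * rng
        counts, edges = np.histogram(z, bins=self.n_bins, range=(lo, hi))
        mids = 0.5 * (edges[:-1] + edges[1:])

        # cubic B-spline basis with spline_df columns; interior knots at
        # equally spaced quantile positions of the grid
        degree = 3
        n_interior = self.spline_df - (degree + 1)
        interior = (
            np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else np.array([])
        )
        self._knots = np.concatenate(
            [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
        )
        self._degree = degree
        basis = self._design(mids)
        design = sm.add_constant(basis)
        model = sm.GLM(counts, design, family=sm.families.Poisson())
        res = model.fit()
        self._coef = res.params

        # normalize exp(eta) to a density by trapezoid rule on a fine grid
        grid = np.linspace(lo, hi, 2001)
        eta = self._eta(grid)
        self._log_norm = float(np.log(np.trapezoid(np.exp(eta - eta.max()), grid)) + eta.max())
        self.lo_, self.hi_ = lo, hi
        self.range_ = hi - lo
        self.z_grid_ = mids
        self.bin_counts_ = counts
        self.deviance_ = float(res.deviance)
        return self

    def _design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self._knots[0], self._knots[-1])
        return interpolate.BSpline.design_matrix(
            x, self._knots, self._degree
        ).toarray()

    def _eta(self, x: np.ndarray) -> np.ndarray:
        return self._coef[0] + self._design(x) @ self._coef[1:]

    # -- evaluation ------------------------------------------------------
    def _check_range(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=float)
        margin = 0.5 * self.range_
        if (z < self.lo_ - margin).any() or (z > self.hi_ + margin).any():
            raise ValueError(
                "z values lie beyond the extrapolation margin of the density fit"
            )
        return z, np.clip(z, self.lo_, self.hi_)

    def log_density(self, z: np.ndarray) -> np.ndarray:
        """``lf(z)``; linear continuation beyond the fitted range."""
        z, zc = self._check_range(z)
        lf = self._eta(zc) - self._log_norm
        return lf + self.derivative(zc) * (z - zc)

    def derivative(self, z: np.ndarray) -> np.ndarray:
        """Analytic ``lf'(z)`` from the spline coefficients."""
        z, zc = self._check_range(z)
        spl = interpolate.BSpline(self._knots, self._coef[1:], self._degree)
        return spl.derivative()(zc)

    def density(self, z: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(z))


@dataclass
class EBFit:
    """A fitted marginal log-density plus the shrunken estimates it implies."""

    density: LindseyDensity
    s2: float
    delta_hat: np.ndarray
    z: np.ndarray

    @property
    def z_grid(self) -> np.ndarray:
        return self.density.z_grid_

    @property
    def bin_counts(self) -> np.ndarray:
        return self.density.bin_counts_


def fit_log_density(z: np.ndarray, n_bins: int = 120, spline_df: int = 7) -> LindseyDensity:
    """Fit the marginal log-density of z scores (Lindsey's method)."""
    return LindseyDensity(n_bins=n_bins, spline_df=spline_df).fit(z)


def estimate_s2(z: np.ndarray, mode: str = "unit") -> float:
    """Variance plugged into Tweedie's formula.

    ``"unit"`` returns 1.0 (the nominal variance of the normal scores);
    ``"central"`` returns the squared normalized interquartile spread of
    z, a robust estimate of the null variance that ignores the tails.
    """
    if mode == "unit":
        return 1.0
    if mode == "central":
        q25, q75 = np.percentile(np.asarray(z, dtype=float), [25, 75])
        iqr_normal = stats.norm.ppf(0.75) - stats.norm.ppf(0.25)
        return float(((q75 - q25) / iqr_normal) ** 2)
    raise ValueError(f"unknown s2 mode {mode!r}; use 'unit' or 'central'")


def tweedie_shrink(z: np.ndarray, density: LindseyDensity, s2: float = 1.0) -> np.ndarray:
    """Tweedie's formula: ``delta_hat = z + s2 * lf'(z)``."""
    if s2 <= 0:
        raise ValueError("s2 must be positive")
    z = np.asarray(z, dtype=float)
    return z + s2 * density.derivative(z)


def standardize_genes(X_eval: np.ndarray, train_stats: GroupStats) -> np.ndarray:
    """Standardize expression with training centering and scale only.

    Each gene is centered at the midpoint of the two training class means
    and divided by the training pooled SD:
    ``W_i = (X_i - (mean0_i + mean1_i)/2) / s_i``. Evaluating held-out
    samples with training parameters avoids information leakage.
    """
    X_eval = np.asarray(X_eval, dtype=float)
    if X_eval.shape[0] != len(train_stats.gene_ids):
        raise ValueError(
            f"gene mismatch: matrix has {X_eval.shape[0]} rows, "
            f"stats cover {len(train_stats.gene_ids)} genes"
        )
    center = 0.5 * (train_stats.mean0 + train_stats.mean1)
    return (X_eval - center[:, None]) / train_stats.pooled_sd[:, None]
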