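"""Combining two tissues' per-gene signals.

Two integration strategies are provided, both producing a per-gene weight
in [0, 1] that measures how much of the evidence for a gene comes from the
first tissue:

* **weighted gene** — the weight is the relative -log p-value from a
  per-gene logistic regression of disease status on expression,
  ``w_i = -log(p_i1) / (-log(p_i1) - log(p_i2))``, and the two expression
  vectors are convexly combined, ``X*_i = w_i X_i1 + (1 - w_i) X_i2``;
* **weighted Z** — the weight is the relative magnitude of the two normal
  scores, ``zw_i = |Z_i1| / (|Z_i1| + |Z_i2|)``, and the scores themselves
  are combined, ``Z^w_i = zw_i Z_i1 + (1 - zw_i) Z_i2``.

Because the two tissues share samples, the combined score's standard
deviation depends on the cross-tissue correlation rho of the score
vectors: ``s_{Z^w} = sqrt(zw^2 + (1-zw)^2 + 2 zw (1-zw) rho)``. It equals
1 exactly when rho = 1 or the weight is degenerate, and is below 1
otherwise — combining partially independent scores contracts the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .dataset import ExpressionDataset, PairedDatasets

logger = logging.getLogger(__name__)

__all__ = [
    "GeneWeights",
    "logistic_lrt_pvalues",
    "per_gene_logistic_pvalues",
    "gene_weights",
    "combine_weighted_genes",
    "z_weights",
    "combine_weighted_z",
    "estimate_rho",
    "weighted_z_sd",
]

_P_FLOOR = 1e-300


@dataclass
class GeneWeights:
    """Per-gene integration weights plus the statistics behind them."""

    gene_ids: list[str]
    method: str  # "weighted_gene" or "weighted_z"
    w: np.ndarray
    p_first: np.ndarray | None = None
    p_second: np.ndarray | None = None
    z_first: np.ndarray | None = None
    z_second: np.ndarray | None = None
    rho: float | None = None
    z_combined: np.ndarray | None = None
    sd_combined: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        cols = {"gene_id": self.gene_ids, "method": self.method, "w": self.w}
        for name in ("p_first", "p_second", "z_first", "z_second", "z_combined", "sd_combined"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)


def logistic_lrt_pvalues(X: np.ndarray, Y: np.ndarray, warn: bool = True) -> np.ndarray:
    """Vectorized per-row logistic likelihood-ratio p-values.

    Row i of ``X`` (shape (M, n)) is one gene's expression and row i of
    ``Y`` (shape (M, n) or (n,), broadcast) its binary labels; the model
    ``logit P(Y=1) = b0 + b1 * x`` is fitted by damped Newton-Raphson
    simultaneously for all rows and compared to the intercept-only null by
    a 1-df likelihood-ratio test. Complete or quasi-complete separation
    makes the MLE diverge; such rows get the clip-floor p-value 1e-300.
    All p-values are clipped to ``[1e-300, 1]``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.broadcast_to(np.asarray(Y, dtype=float), X.shape)
    M = X.shape[0]

    b0 = np.zeros(M)
    b1 = np.zeros(M)
    converged = np.zeros(M, dtype=bool)
    for _ in range(40):
        eta = b0[:, None] + b1[:, None] * X
        mu = special.expit(eta)
        wgt = mu * (1.0 - mu)
        r = Y - mu
        g0 = r.sum(axis=1)
        g1 = (r * X).sum(axis=1)
        h00 = wgt.sum(axis=1)
        h01 = (wgt * X).sum(axis=1)
        h11 = (wgt * X * X).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(det < 1e-12, 1e-12, det)
        s0 = (h11 * g0 - h01 * g1) / det
        s1 = (h00 * g1 - h01 * g0) / det
        # damp huge steps to keep the iteration stable near separation
        step = np.maximum(np.abs(s0), np.abs(s1))
        with np.errstate(divide="ignore"):
            damp = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        b0 += damp * s0
        b1 += damp * s1
        done = step < 1e-10
        converged |= done
        if done.all():
            break

    separated = (~converged) | (np.abs(b1) > 25.0)
    if separated.any() and warn:
        logger.warning(
            "%d gene(s) show (near-)complete separation; p set to clip floor",
            int(separated.sum()),
        )

    eta = b0[:, None] + b1[:, None] * X
    ll_full = np.sum(Y * eta - np.logaddexp(0.0, eta), axis=1)
    pbar = Y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_null = X.shape[1] * np.where(
            (pbar > 0) & (pbar < 1),
            pbar * np.log(np.where(pbar > 0, pbar, 1.0))
            + (1 - pbar) * np.log(np.where(pbar < 1, 1 - pbar, 1.0)),
            0.0,
        )
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(separated, _P_FLOOR, p)
    return np.clip(p, _P_FLOOR, 1.0)


def per_gene_logistic_pvalues(dataset: ExpressionDataset) -> np.ndarray:
    """Likelihood-ratio p-values from per-gene logistic regressions of
    disease status on expression (see :func:`logistic_lrt_pvalues`)."""
    dataset.require_class_counts(1)
    return logistic_lrt_pvalues(dataset.X, dataset.y.astype(float))


def gene_weights(p_first: np.ndarray, p_second: np.ndarray) -> np.ndarray:
    """Relative -log p-value weight of the first tissue per gene.

    ``w_i = -log(p_i1) / (-log(p_i1) - log(p_i2))``; when both p-values
    are exactly 1 the ratio is 0/0 and the weight defaults to 0.5 (equal
    evidence). The weight is invariant to the base of the logarithm.
    """
    p_first = np.asarray(p_first, dtype=float)
    p_second = np.asarray(p_second, dtype=float)
    for name, p in (("p_first", p_first), ("p_second", p_second)):
        if (p <= 0).any() or (p > 1).any():
            raise ValueError(f"{name} must lie in (0, 1]")
    a = -np.log(p_first)
    b = -np.log(p_second)
    total = a + b
    with np.errstate(invalid="ignore"):
        w = np.where(total > 0, a / np.where(total > 0, total, 1.0), 0.5)
    return w


def combine_weighted_genes(pair: PairedDatasets, w: np.ndarray) -> ExpressionDataset:
    """Convex per-gene combination ``X* = w X_first + (1 - w) X_second``."""
    w = np.asarray(w, dtype=float)
    if w.shape != (len(pair.gene_ids),):
        raise ValueError("one weight per gene required")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    X_star = w[:, None] * pair.first.X + (1.0 - w)[:, None] * pair.second.X
    return replace(pair.first, X=X_star, tissue="weighted_gene")


def z_weights(z_first: np.ndarray, z_second: np.ndarray) -> np.ndarray:
    """Relative |Z| weight: ``zw = |Z_first| / (|Z_first| + |Z_second|)``.

    Both scores zero gives 0/0, resolved to 0.5.
    """
    z_first = np.asarray(z_first, dtype=float)
    z_second = np.asarray(z_second, dtype=float)
    if not (np.isfinite(z_first).all() and np.isfinite(z_second).all()):
        raise ValueError("z scores must be finite")
    a = np.abs(z_first)
    total = a + np.abs(z_second)
    return np.where(total > 0, a / np.where(total > 0, total, 1.0), 0.5)


def combine_weighted_z(
    z_first: np.ndarray, z_second: np.ndarray, zw: np.ndarray
) -> np.ndarray:
    """Weighted score ``Z^w = zw * Z_first + (1 - zw) * Z_second``."""
    z_first = np.asarray(z_first, dtype=float)
    z_second = np.asarray(z_second, dtype=float)
    zw = np.asarray(zw, dtype=float)
    if not (z_first.shape == z_second.shape == zw.shape):
        raise ValueError("z vectors and weights must be aligned")
    if (zw < 0).any() or (zw > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    return zw * z_first + (1.0 - zw) * z_second


def estimate_rho(z_first: np.ndarray, z_second: np.ndarray) -> float:
    """Pearson correlation of the two score vectors across genes."""
    z_first = np.asarray(z_first, dtype=float)
    z_second = np.asarray(z_second, dtype=float)
    if z_first.size < 3:
        raise ValueError("need at least 3 genes to estimate rho")
    if np.std(z_first) == 0 or np.std(z_second) == 0:
        raise ValueError("cannot correlate a constant score vector")
    return float(np.clip(stats.pearsonr(z_first, z_second)[0], -1.0, 1.0))


def weighted_z_sd(zw: np.ndarray, rho: float) -> np.ndarray:
    """SD of the weighted score: ``sqrt(zw^2 + (1-zw)^2 + 2 zw (1-zw) rho)``."""
    zw = np.asarray(zw, dtype=float)
    if (zw < 0).any() or (zw > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    val = zw**2 + (1.0 - zw) ** 2 + 2.0 * zw * (1.0 - zw) * rho
    return np.sqrt(np.maximum(val, 0.0))
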