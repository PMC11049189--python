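"""Gene selection, the sign prediction rule, cross-validation and scoring.

The functional surface here wraps the estimator classes in
:mod:`dualeb.estimators` for workflows that start from
:class:`~dualeb.dataset.ExpressionDataset` objects: fitting the top-k
sign rule, repeated stratified 50/50 train/test splits, misclassification
error, rank-based AUC and top-k recovery of known differential genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from . import eb, integration
from .dataset import ExpressionDataset, PairedDatasets
from .estimators import (
    EmpiricalBayesClassifier,
    WeightedGeneClassifier,
    WeightedZClassifier,
    paired_design_matrix,
)

__all__ = [
    "PredictionRule",
    "EvaluationResult",
    "select_top_genes",
    "fit_prediction_rule",
    "predict_scores",
    "cross_validate",
    "roc_auc",
    "topk_recovery",
    "rank_genes",
]

METHODS = ("single", "weighted_gene", "weighted_z")


@dataclass
class PredictionRule:
    """Frozen output of a training fit: the gene set I and its coefficients."""

    selected_genes: list[str]
    coefficients: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    method: str = "single"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if len(self.selected_genes) != len(self.coefficients) or not self.selected_genes:
            raise ValueError("need one coefficient per selected gene (at least one)")
        if (np.asarray(self.scale) <= 0).any():
            raise ValueError("standardization scale must be positive")


@dataclass
class EvaluationResult:
    """Per-repeat CV errors plus pooled ROC/AUC and optional top-k recovery."""

    per_repeat_errors: list[float]
    mean_error: float
    sd_error: float
    auc: float
    roc_points: list[tuple[float, float]]
    topk_counts: dict[int, int] = field(default_factory=dict)
    seed: int | None = None
    n_repeats: int = 0
    method: str = "single"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_repeat_errors": [float(e) for e in self.per_repeat_errors],
            "mean_error": float(self.mean_error),
            "sd_error": float(self.sd_error),
            "auc": float(self.auc),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "topk_counts": {int(k): int(v) for k, v in self.topk_counts.items()},
            "seed": self.seed,
            "n_repeats": self.n_repeats,
        }


def select_top_genes(delta_hat: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k genes with largest ``|delta_hat|``.

    Ordered by decreasing magnitude; ties broken by ascending input index
    (stable sort).
    """
    delta_hat = np.asarray(delta_hat, dtype=float)
    if not 1 <= k <= delta_hat.size:
        raise ValueError(f"k must be in [1, {delta_hat.size}] (got {k})")
    return np.argsort(-np.abs(delta_hat), kind="stable")[:k]


def fit_prediction_rule(
    train: ExpressionDataset,
    k: int = 100,
    n_bins: int = 120,
    spline_df: int = 7,
    s2_mode: str = "unit",
) -> PredictionRule:
    """Fit the single-dataset empirical-Bayes sign rule on training data."""
    clf = EmpiricalBayesClassifier(
        k=k, n_bins=n_bins, spline_df=spline_df, s2_mode=s2_mode
    ).fit(train.X.T, train.y)
    return PredictionRule(
        selected_genes=[train.gene_ids[i] for i in clf.selected_],
        coefficients=clf.coef_,
        center=clf.center_,
        scale=clf.scale_,
        method="single",
    )


def predict_scores(rule: PredictionRule, X_test: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Per-sample scores ``sum_i delta_hat_i * W_ij`` for a test matrix.

    ``X_test`` is genes x samples with rows named by ``gene_ids``; every
    selected gene of the rule must be present.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    try:
        rows = [index[g] for g in rule.selected_genes]
    except KeyError as err:
        raise ValueError(f"test matrix is missing selected gene {err.args[0]!r}") from None
    W = (np.asarray(X_test, dtype=float)[rows] - rule.center[:, None]) / rule.scale[:, None]
    return rule.coefficients @ W


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """Rank-based (Mann-Whitney) AUC with tie correction, plus ROC points.

    AUC is the probability that a random disease sample scores above a
    random normal sample, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def topk_recovery(
    ranking: list[str] | np.ndarray,
    truth: set[str],
    k: int,
    truth_first: set[str] | None = None,
    truth_second: set[str] | None = None,
) -> dict:
    """Number of true differential genes among the top-k of a ranking.

    With tissue-annotated truth sets, also reports per-tissue counts
    (a gene differential in both tissues counts in both).
    """
    ranking = list(ranking)
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must be in [1, {len(ranking)}] (got {k})")
    top = set(ranking[:k])
    out = {"count": len(top & set(truth))}
    if truth_first is not None:
        out["first"] = len(top & set(truth_first))
    if truth_second is not None:
        out["second"] = len(top & set(truth_second))
    return out


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (0, 1):
        members = np.flatnonzero(y == label)
        perm = rng.permutation(members)
        n_train = int(round(train_frac * members.size))
        n_train = min(max(n_train, 2), members.size - 2)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _make_classifier(method: str, k: int, eb_options: dict, precomputed=None):
    if method == "single":
        return EmpiricalBayesClassifier(k=k, **eb_options)
    if method == "weighted_gene":
        return WeightedGeneClassifier(k=k, precomputed_weights=precomputed, **eb_options)
    if method == "weighted_z":
        return WeightedZClassifier(k=k, precomputed_weights=precomputed, **eb_options)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _full_data_weights(pair: PairedDatasets, method: str) -> np.ndarray:
    if method == "weighted_gene":
        p1 = integration.per_gene_logistic_pvalues(pair.first)
        p2 = integration.per_gene_logistic_pvalues(pair.second)
        return integration.gene_weights(p1, p2)
    stats1 = eb.compute_group_stats(pair.first)
    stats2 = eb.compute_group_stats(pair.second)
    return integration.z_weights(stats1.z, stats2.z)


def cross_validate(
    data: ExpressionDataset | PairedDatasets,
    method: str = "single",
    k: int = 100,
    n_repeats: int = 5,
    train_frac: float = 0.5,
    seed: int = 0,
    paper_mode: bool = False,
    auc_per_repeat: bool = False,
    **eb_options,
) -> EvaluationResult:
    """Repeated stratified train/test evaluation of one method.

    Each repeat draws a stratified ``train_frac`` split (4/4 per class per
    half at n = 16), refits the full pipeline — statistics, density,
    shrinkage, gene selection and, for the integration methods, weights —
    on the training half only, and scores the held-out half. Reported are
    per-repeat misclassification errors, their mean and sample SD, and the
    ROC/AUC of the test scores pooled over repeats (``auc_per_repeat=True``
    averages per-repeat AUCs instead).

    ``paper_mode=True`` computes the integration weights once from all
    samples instead of per training fold, mirroring protocols that treat
    weighting as a preprocessing step.

    For ``weighted_z`` the fitted rule is applied separately to each
    tissue's standardized test data; the two test errors are averaged per
    repeat and the reported AUC is the mean of the two tissues' AUCs.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    if method == "single":
        if not isinstance(data, ExpressionDataset):
            raise TypeError("method 'single' expects an ExpressionDataset")
        Xs = data.X.T
        y = data.y
    else:
        if not isinstance(data, PairedDatasets):
            raise TypeError(f"method {method!r} expects a PairedDatasets")
        Xs = paired_design_matrix(data)
        y = data.y

    for label in (0, 1):
        if int((y == label).sum()) < 4:
            raise ValueError(
                "each class needs at least 4 samples so both train and test "
                "halves keep 2 per class"
            )

    precomputed = _full_data_weights(data, method) if (paper_mode and method != "single") else None

    rng = np.random.default_rng(seed)
    errors: list[float] = []
    pooled: list[tuple[np.ndarray, np.ndarray]] = []  # scores (or per-tissue), labels
    repeat_aucs: list[float] = []
    for _ in range(n_repeats):
        tr, te = _stratified_split(y, train_frac, rng)
        clf = _make_classifier(method, k, eb_options, precomputed)
        clf.fit(Xs[tr], y[tr])
        if method == "weighted_z":
            s1, s2 = clf.decision_function_per_tissue(Xs[te])
            e1 = float(np.mean((s1 > 0).astype(int) != y[te]))
            e2 = float(np.mean((s2 > 0).astype(int) != y[te]))
            errors.append(0.5 * (e1 + e2))
            pooled.append((np.vstack([s1, s2]), y[te]))
            if auc_per_repeat:
                repeat_aucs.append(
                    0.5 * (roc_auc(s1, y[te])[0] + roc_auc(s2, y[te])[0])
                )
        else:
            s = clf.decision_function(Xs[te])
            errors.append(float(np.mean((s > 0).astype(int) != y[te])))
            pooled.append((s, y[te]))
            if auc_per_repeat:
                repeat_aucs.append(roc_auc(s, y[te])[0])

    labels_all = np.concatenate([lab for _, lab in pooled])
    if method == "weighted_z":
        s1_all = np.concatenate([s[0] for s, _ in pooled])
        s2_all = np.concatenate([s[1] for s, _ in pooled])
        auc1, roc1 = roc_auc(s1_all, labels_all)
        auc2, _ = roc_auc(s2_all, labels_all)
        auc_pooled = 0.5 * (auc1 + auc2)
        roc_points = roc1
    else:
        scores_all = np.concatenate([s for s, _ in pooled])
        auc_pooled, roc_points = roc_auc(scores_all, labels_all)
    auc = float(np.mean(repeat_aucs)) if auc_per_repeat else auc_pooled

    errors_arr = np.asarray(errors)
    return EvaluationResult(
        per_repeat_errors=errors,
        mean_error=float(errors_arr.mean()),
        sd_error=float(errors_arr.std(ddof=1)) if n_repeats > 1 else 0.0,
        auc=auc,
        roc_points=roc_points,
        seed=seed,
        n_repeats=n_repeats,
        method=method,
    )


def rank_genes(
    data: ExpressionDataset | PairedDatasets,
    method: str = "single",
    **eb_options,
):
    """Rank all genes of a dataset (or pair) by ``|delta_hat|``.

    Returns a DataFrame ordered from strongest to weakest gene, carrying
    the statistics behind the ranking (t, z, weights where applicable).
    """
    import pandas as pd

    if method == "single":
        if not isinstance(data, ExpressionDataset):
            raise TypeError("method 'single' expects an ExpressionDataset")
        clf = EmpiricalBayesClassifier(k=data.n_genes, **eb_options).fit(data.X.T, data.y)
        frame = pd.DataFrame(
            {
                "gene_id": data.gene_ids,
                "t": clf.stats_.t,
                "z": clf.stats_.z,
                "delta_hat": clf.delta_hat_,
            }
        )
    elif method == "weighted_gene":
        clf = WeightedGeneClassifier(k=len(data.gene_ids), **eb_options).fit(
            paired_design_matrix(data), data.y
        )
        frame = pd.DataFrame(
            {
                "gene_id": data.gene_ids,
                "w": clf.weights_,
                "p_first": clf.p_first_,
                "p_second": clf.p_second_,
                "t": clf.stats_.t,
                "z": clf.stats_.z,
                "delta_hat": clf.delta_hat_,
            }
        )
    elif method == "weighted_z":
        clf = WeightedZClassifier(k=len(data.gene_ids), **eb_options).fit(
            paired_design_matrix(data), data.y
        )
        frame = pd.DataFrame(
            {
                "gene_id": data.gene_ids,
                "zw": clf.z_weights_,
                "z_first": clf.stats_first_.z,
                "z_second": clf.stats_second_.z,
                "z_combined": clf.z_combined_,
                "sd_combined": clf.sd_combined_,
                "delta_hat": clf.delta_hat_,
            }
        )
        frame.attrs["rho"] = clf.rho_
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    order = select_top_genes(frame["delta_hat"].to_numpy(), len(frame))
    return frame.iloc[order].reset_index(drop=True)
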