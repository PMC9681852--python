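"""Quantitative evaluation: per-cell Pearson correlation and clustering quality.

Per-cell Pearson uses the (m-1) sample convention

    rho(A, B) = 1/(m-1) * sum_i ((A_i - mu_A)/sigma_A) * ((B_i - mu_B)/sigma_B)

with sigma the sample standard deviation, which is the standard Pearson
correlation coefficient.  Clustering quality runs k-means (k-means++
seeding, Euclidean distance) with k equal to the number of ground-truth
classes, maps predicted clusters onto truth labels by a maximum-agreement
bijection on the contingency table, and reports accuracy, normalized mutual
information, adjusted Rand and the Hubert Gamma statistic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .errors import ParameterError
from .io import ExpressionMatrix


def pearson_per_cell(reference: ExpressionMatrix, estimate: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation of every cell's expression vector across the two matrices.

    Cells with zero variance in either matrix get NaN (with a warning).
    """
    if reference.shape != estimate.shape:
        raise ParameterError(
            f"shape mismatch: reference {reference.shape} vs estimate {estimate.shape}"
        )
    A = reference.values
    B = estimate.values
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    va = (Ac ** 2).sum(axis=1)
    vb = (Bc ** 2).sum(axis=1)
    denom = np.sqrt(va * vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Ac * Bc).sum(axis=1) / denom
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance cells; Pearson set to NaN")
        rho[degenerate] = np.nan
    return rho


def mean_pearson(reference: ExpressionMatrix, estimate: ExpressionMatrix) -> float:
    """Mean per-cell Pearson, excluding NaN (zero-variance) cells."""
    return float(np.nanmean(pearson_per_cell(reference, estimate)))


def percent_change(rho_method: float, rho_observed: float) -> float:
    """Percentage improvement of an imputation method over the observed data."""
    if rho_observed == 0:
        raise ParameterError("percent change is undefined for rho_observed == 0")
    return 100.0 * (rho_method - rho_observed) / rho_observed


def best_map(truth: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel predicted clusters by maximum-agreement bijection onto truth labels.

    Returns (mapped_predicted_labels, contingency_matrix); ties resolve to
    the lowest index via the deterministic assignment solver.
    """
    C = contingency_matrix(truth, predicted)
    truth_classes = np.unique(truth)
    row_ind, col_ind = linear_sum_assignment(-C)
    mapping = {col: truth_classes[row] for row, col in zip(row_ind, col_ind)}
    pred_classes = np.unique(predicted)
    for j, cls in enumerate(pred_classes):
        if j not in mapping:  # more predicted clusters than truth classes
            mapping[j] = truth_classes[0]
    mapped = np.array([mapping[j] for j in np.searchsorted(pred_classes, predicted)])
    return mapped, C


def hubert_gamma(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Hubert's Gamma: correlation of pair co-membership between two partitions."""
    C = contingency_matrix(truth, predicted).astype(float)
    n = C.sum()
    M = n * (n - 1) / 2.0
    a = (np.square(C).sum() - n) / 2.0  # pairs together in both partitions
    P = (np.square(C.sum(axis=1)).sum() - n) / 2.0
    Q = (np.square(C.sum(axis=0)).sum() - n) / 2.0
    denom = P * Q * (M - P) * (M - Q)
    if denom <= 0:
        return 0.0
    return float((M * a - P * Q) / np.sqrt(denom))


@dataclasses.dataclass
class ClusterReport:
    """k-means clustering agreement with ground truth over repeated initializations."""

    accuracy: float
    accuracy_mean: float
    accuracy_sd: float
    nmi: float
    adjusted_rand: float
    hubert: float
    n_clusters: int
    n_init: int


def cluster_metrics(
    data: ExpressionMatrix | np.ndarray,
    truth_labels: np.ndarray,
    n_init: int = 1000,
    seed: int = 0,
) -> ClusterReport:
    """k-means clustering quality against ground-truth labels.

    k-means (k = number of truth classes, k-means++ seeding) is run
    ``n_init`` times with independent seeds; per-run accuracies give the
    mean/SD, and the best-inertia run provides the headline accuracy, NMI,
    adjusted Rand and Hubert indices (all computed after best-map
    relabeling where label identity matters).
    """
    X = data.values if isinstance(data, ExpressionMatrix) else np.asarray(data, dtype=float)
    truth = np.asarray(truth_labels)
    k = len(np.unique(truth))
    if k < 2:
        raise ParameterError("need at least 2 ground-truth classes")
    if X.shape[0] < k:
        raise ParameterError(f"{X.shape[0]} samples for {k} clusters")
    if X.shape[0] != len(truth):
        raise ParameterError("labels length does not match number of samples")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_init)
    best_labels = None
    best_inertia = np.inf
    accuracies = np.empty(n_init)
    for i, s in enumerate(run_seeds):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=int(s)).fit(X)
        mapped, _ = best_map(truth, km.labels_)
        accuracies[i] = float((mapped == truth).mean())
        if km.inertia_ < best_inertia:
            best_inertia = km.inertia_
            best_labels = km.labels_
    mapped, _ = best_map(truth, best_labels)
    return ClusterReport(
        accuracy=float((mapped == truth).mean()),
        accuracy_mean=float(accuracies.mean()),
        accuracy_sd=float(accuracies.std(ddof=1)) if n_init > 1 else 0.0,
        nmi=float(normalized_mutual_info_score(truth, best_labels)),
        adjusted_rand=float(adjusted_rand_score(truth, best_labels)),
        hubert=hubert_gamma(truth, best_labels),
        n_clusters=k,
        n_init=n_init,
    )


@dataclasses.dataclass
class EvaluationReport:
    """Full evaluation of an imputed matrix against its reference."""

    pearson_per_cell: np.ndarray
    mean_pearson: float
    percent_change: float | None = None
    clusters: ClusterReport | None = None


def evaluate_imputation(
    reference: ExpressionMatrix,
    imputed: ExpressionMatrix,
    observed: ExpressionMatrix | None = None,
    labels: np.ndarray | None = None,
    embedding: np.ndarray | None = None,
    n_init: int = 50,
    seed: int = 0,
) -> EvaluationReport:
    """Convenience wrapper combining correlation and clustering evaluation.

    ``embedding`` (e.g. PCA-reduced imputed data) is clustered when given;
    otherwise the imputed matrix itself is.
    """
    rho = pearson_per_cell(reference, imputed)
    mean_rho = float(np.nanmean(rho))
    change = None
    if observed is not None:
        change = percent_change(mean_rho, mean_pearson(reference, observed))
    clusters = None
    if labels is not None:
        data = embedding if embedding is not None else imputed
        clusters = cluster_metrics(data, labels, n_init=n_init, seed=seed)
    return EvaluationReport(
        pearson_per_cell=rho, mean_pearson=mean_rho, percent_change=change, clusters=clusters
    )
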