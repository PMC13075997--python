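"""Gene-class assignment.

Three orthogonal label axes are produced per gene:

* activity — ``active`` iff the RNAPIIS2P density log2(1 + RPK) reaches a
  threshold (default 4, inclusive);
* occupancy — k-means (k = 3) on the gene-body metagene matrix of
  coverage-normalized factor signal; the cluster with the highest mean
  signal is ``U2AF2_high``, the remaining clusters merge into
  ``U2AF2_low``;
* RNase sensitivity — a defined differential-enrichment procedure on
  per-gene fragment counts (control vs RNase-treated replicates):
  median-of-ratios size factors, log2 fold change with a 0.5 pseudocount,
  a two-sided Welch t-test on log2 normalized counts, Benjamini-Hochberg
  adjustment, and the label ``rnase_sensitive`` iff log2FC <= -1 and
  adjusted p < 0.05 (signal decreases on sensitive genes). This is a
  deliberately simple, fully reproducible test, not a negative-binomial
  GLM; see the methods note for its power characteristics.

The k-means implementation is Lloyd's algorithm with k-means++
initialization from an explicit seed, so labels are identical across runs
and platforms given the same seed and input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 4.0


def classify_activity(density, threshold: float = ACTIVITY_THRESHOLD):
    """'active' iff density >= threshold (inclusive). Vectorized over arrays."""
    arr = np.asarray(density, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("density = log2(1 + RPK) must be >= 0")
    labels = np.where(arr >= threshold, "active", "inactive")
    if labels.ndim == 0:
        return str(labels)
    return labels


# ---------------------------------------------------------------------------
# k-means


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    idx = int(rng.integers(n))
    centroids[0] = X[idx]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[j] = X[idx]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def kmeans(
    matrix, k: int = 3, seed: int = 0, max_iter: int = 300
) -> KMeansResult:
    """Lloyd's algorithm, Euclidean distance, k-means++ initialization.

    Deterministic given seed; iterates to an assignment fixed point or
    ``max_iter``. An emptied cluster is re-seeded from the point farthest
    from its centroid.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (genes x bins)")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct rows ({n_distinct})")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            sel = new_labels == j
            if not sel.any():
                # documented rule: re-seed an empty cluster from the point
                # farthest from its assigned centroid
                far = d2[np.arange(len(X)), new_labels].argmax()
                centroids[j] = X[far]
                new_labels[far] = j
                sel = new_labels == j
            centroids[j] = X[sel].mean(axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return KMeansResult(labels=labels, centroids=centroids, inertia=inertia, n_iter=it)


def assign_high_low(
    labels: np.ndarray, matrix, high_label: str = "U2AF2_high", low_label: str = "U2AF2_low"
) -> np.ndarray:
    """Merge k clusters into a two-way split: highest-mean cluster is high.

    Ties in cluster mean signal break toward the larger cluster (logged).
    """
    X = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    means = np.array([X[labels == j].mean() for j in ks])
    sizes = np.array([(labels == j).sum() for j in ks])
    best = means.max()
    top = np.flatnonzero(means == best)
    if len(top) > 1:
        logger.warning("assign_high_low: tie in cluster means; breaking by size")
        top = [top[np.argmax(sizes[top])]]
    high_cluster = ks[top[0]]
    return np.where(labels == high_cluster, high_label, low_label)


# ---------------------------------------------------------------------------
# differential enrichment (simplified, fully specified substitute)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Per-sample median, over reference genes, of count / geometric mean of
    the gene's row; genes with any zero count are excluded from the
    reference.
    """
    counts = np.asarray(counts, dtype=np.float64)
    ref = np.all(counts > 0, axis=1)
    if not ref.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    log_geo = np.log(counts[ref]).mean(axis=1)
    ratios = np.log(counts[ref]) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def differential_enrichment(
    counts_control,
    counts_treated,
    gene_ids=None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential enrichment of treated vs control per-gene counts.

    Returns a DataFrame with normalized base mean, log2 fold change
    (treated/control, 0.5 pseudocount), Welch-t p-value on log2 normalized
    counts, BH-adjusted p-value, and an ``rnase_label`` column:
    ``rnase_sensitive`` iff log2FC <= -lfc_threshold and padj < alpha,
    else ``chromatin_bound``. All-zero genes get p = 1.
    """
    C = np.asarray(counts_control, dtype=np.float64)
    T = np.asarray(counts_treated, dtype=np.float64)
    if C.ndim != 2 or T.ndim != 2 or C.shape[0] != T.shape[0]:
        raise ValueError("count matrices must be genes x replicates with equal gene counts")
    if C.shape[1] < 2 or T.shape[1] < 2:
        raise ValueError("at least 2 replicates per condition required")
    if np.any(C < 0) or np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    all_counts = np.hstack([C, T])
    sf = size_factors(all_counts)
    norm = all_counts / sf
    nC = C.shape[1]
    normC, normT = norm[:, :nC], norm[:, nC:]
    lfc = np.log2((normT.mean(axis=1) + 0.5) / (normC.mean(axis=1) + 0.5))
    logC = np.log2(normC + 0.5)
    logT = np.log2(normT + 0.5)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        _, pvals = sps.ttest_ind(logT, logC, axis=1, equal_var=False)
    # zero within-group variance: p = 0 if means differ, 1 if identical
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        same = np.isclose(logT.mean(axis=1), logC.mean(axis=1))
        pvals = np.where(degenerate, np.where(same, 1.0, 0.0), pvals)
    all_zero = np.all(all_counts == 0, axis=1)
    pvals = np.where(all_zero, 1.0, pvals)
    padj = benjamini_hochberg(pvals)
    sensitive = (lfc <= -lfc_threshold) & (padj < alpha)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(C.shape[0])]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "rnase_label": np.where(sensitive, "rnase_sensitive", "chromatin_bound"),
        }
    )


# ---------------------------------------------------------------------------
# quantile groupings


def quantile_split(values, q: int) -> np.ndarray:
    """Group indices (0-based) by empirical quantile boundaries.

    Ties at a boundary go to the lower group. Degenerate (constant) values
    raise, as do q < 2 or q > n.
    """
    v = np.asarray(values, dtype=np.float64)
    if q < 2:
        raise ValueError("q must be >= 2")
    if q > v.size:
        raise ValueError(f"q={q} exceeds number of values ({v.size})")
    if np.all(v == v[0]):
        raise ValueError("constant values: quantile groups undefined")
    inner = np.quantile(v, np.arange(1, q) / q)
    return np.searchsorted(inner, v, side="left")


def build_gene_class_table(
    gene_ids,
    activity_labels,
    occupancy_labels=None,
    rnase_labels=None,
    quantile_groups: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene class table; missing axes become 'not_tested'."""
    n = len(gene_ids)
    df = pd.DataFrame({"gene_id": list(gene_ids), "activity": list(activity_labels)})
    df["occupancy"] = list(occupancy_labels) if occupancy_labels is not None else ["not_tested"] * n
    df["rnase"] = list(rnase_labels) if rnase_labels is not None else ["not_tested"] * n
    for name, groups in (quantile_groups or {}).items():
        df[name] = groups
    return df
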