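"""Signature validation: linear-SVM train/test transfer, hierarchical
clustering, and the Biological Homogeneity / Stability cluster-validity
indices (BHI / BSI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.svm import SVC

from .io import ExpressionMatrix

__all__ = [
    "ClassificationReport",
    "ClusterValidityReport",
    "svm_linear_eval",
    "hcluster_cut",
    "bhi",
    "bsi",
]

log = logging.getLogger(__name__)


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    genes_used: list[str]
    genes_dropped: list[str]


def _zscore_genes(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - values.mean(axis=1, keepdims=True)) / sd


def svm_linear_eval(
    train: ExpressionMatrix, test: ExpressionMatrix, genes: list[str]
) -> ClassificationReport:
    """Linear SVM (fixed C = 1) trained on one cohort, tested on another.

    Signature genes absent from either cohort are dropped and reported; each
    cohort is per-gene z-scored independently. Cancer is the positive class.
    """
    if not genes:
        raise ValueError("empty signature: nothing to classify with")
    classes = set(c for c in train.sample_class if c != "unknown")
    if len(classes) < 2:
        raise ValueError("training cohort must contain both classes")
    in_both = set(train.gene_ids) & set(test.gene_ids)
    used = [g for g in genes if g in in_both]
    dropped = [g for g in genes if g not in in_both]
    if dropped:
        log.info("signature genes absent from a cohort, excluded: %s", dropped)
    if not used:
        raise ValueError("no signature gene is present in both cohorts")

    Xtr = _zscore_genes(train.subset_genes(used).values).T
    Xte = _zscore_genes(test.subset_genes(used).values).T
    ytr = np.array([1 if c == "cancer" else 0 for c in train.sample_class])
    yte = np.array([1 if c == "cancer" else 0 for c in test.sample_class])

    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)

    tp = int(np.sum((pred == 1) & (yte == 1)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    n = tp + fp + tn + fn
    return ClassificationReport(
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        genes_used=used,
        genes_dropped=dropped,
    )


def hcluster_cut(
    data: np.ndarray,
    k: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of rows; returns (labels 0..k-1, merge tree)."""
    data = np.asarray(data, dtype=float)
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds the number of objects ({data.shape[0]})")
    Z = linkage(data, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


@dataclass
class ClusterValidityReport:
    bhi: float
    bsi: float
    linkage: str
    metric: str
    k: int


def bhi(stat_clusters, bio_classes) -> float:
    """Biological Homogeneity Index.

    Mean, over clusters with at least two members, of the fraction of
    ordered within-cluster pairs sharing a biological class.
    """
    stat_clusters = np.asarray(stat_clusters)
    bio_classes = np.asarray(bio_classes)
    if stat_clusters.shape != bio_classes.shape:
        raise ValueError("cluster and class label vectors must align")
    terms = []
    for c in np.unique(stat_clusters):
        members = bio_classes[stat_clusters == c]
        nj = members.size
        if nj < 2:
            continue
        same = sum(np.sum(members == b) - 1 for b in members)
        terms.append(same / (nj * (nj - 1)))
    if not terms:
        raise ValueError("no cluster has at least 2 annotated members")
    return float(np.mean(terms))


def bsi(
    data: np.ndarray,
    bio_classes,
    clusterer=None,
    k: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> float:
    """Biological Stability Index under leave-one-column-out reclustering.

    The objects (rows) are clustered on the full data (D0) and on each
    column-deleted copy (Dl); for each biological class with >= 2 members the
    mean relative overlap |D0(g) ∩ Dl(g')| / |D0(g)| over ordered member
    pairs g != g' is averaged over deletions, then over classes. D0(g) is
    g's full-data co-cluster set, including g itself.
    """
    data = np.asarray(data, dtype=float)
    bio_classes = np.asarray(bio_classes)
    n, L = data.shape
    if L < 2:
        raise ValueError("BSI needs at least 2 conditions (columns)")
    if bio_classes.shape != (n,):
        raise ValueError("class labels must align with the data rows")
    if clusterer is None:
        clusterer = lambda d: hcluster_cut(d, k=k, method=method, metric=metric)[0]

    full = np.asarray(clusterer(data))
    M0 = full[:, None] == full[None, :]  # co-cluster indicator, diag True
    size0 = M0.sum(axis=1).astype(float)

    classes = [b for b in np.unique(bio_classes) if np.sum(bio_classes == b) >= 2]
    if not classes:
        raise ValueError("no biological class has at least 2 members")

    per_class = np.zeros(len(classes))
    for l in range(L):
        red = np.asarray(clusterer(np.delete(data, l, axis=1)))
        Ml = red[:, None] == red[None, :]
        overlap = (M0.astype(float) @ Ml.astype(float)) / size0[:, None]
        for ci, b in enumerate(classes):
            idx = np.nonzero(bio_classes == b)[0]
            sub = overlap[np.ix_(idx, idx)]
            nk = idx.size
            per_class[ci] += (sub.sum() - np.trace(sub)) / (nk * (nk - 1))
    per_class /= L
    return float(per_class.mean())
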