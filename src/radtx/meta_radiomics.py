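"""Meta-radiomic feature extraction.

Radiomic features (points in sample space) are clustered with an iterative
K-means; the number of clusters is chosen over a wide range by silhouette and
Davies-Bouldin scores; clusters whose mean pairwise Spearman correlation
(homogeneity score) exceeds a threshold are represented by the member feature
nearest their centroid — the meta-radiomic feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .io import FeatureTable

__all__ = [
    "ClusterModel",
    "KSelectionTable",
    "MetaRadiomicsSignature",
    "prepare_features",
    "kmeans_fit",
    "select_k",
    "homogeneity_scores",
    "extract_meta_features",
    "pca_project",
]

log = logging.getLogger(__name__)


def prepare_features(t: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Drop constant features and z-score the rest per feature across samples."""
    if t.n_samples < 2:
        raise ValueError("feature preparation requires at least 2 samples")
    keep = np.ptp(t.values, axis=0) > 0  # exact constancy, immune to fp noise in std
    if not keep.any():
        raise ValueError("all features are constant across samples")
    dropped = [f for f, k in zip(t.feature_ids, keep) if not k]
    vals = t.values[:, keep]
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    kept_ids = [f for f, k in zip(t.feature_ids, keep) if k]
    kept_cls = [c for c, k in zip(t.feature_class, keep) if k]
    return FeatureTable(list(t.sample_ids), kept_ids, vals, kept_cls), dropped


@dataclass
class ClusterModel:
    k: int
    feature_ids: list[str]
    labels: np.ndarray  # per-feature cluster index, aligned with feature_ids
    centroids: np.ndarray  # k x n_samples, standardized space
    inertia: float
    seed: int

    @property
    def assignment(self) -> dict[str, int]:
        return {f: int(c) for f, c in zip(self.feature_ids, self.labels)}

    def members(self, cluster: int) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.labels) if c == cluster]


def _init_centroids(points: np.ndarray, k: int, rng: np.random.Generator, init: str):
    n = points.shape[0]
    if init == "random":
        return points[rng.choice(n, size=k, replace=False)].copy()
    if init != "kmeans++":
        raise ValueError("init must be 'kmeans++' or 'random'")
    # k-means++: each next centroid sampled with probability proportional to
    # its squared distance from the nearest centroid chosen so far
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = ((points - centroids[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[c] = points[rng.integers(n)]
            continue
        centroids[c] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((points - centroids[c]) ** 2).sum(axis=1))
    return centroids


def _lloyd(points: np.ndarray, k: int, n_iter: int, rng: np.random.Generator,
           init: str = "kmeans++"):
    """One seeded Lloyd run (squared Euclidean).

    Empty clusters are repaired by reseeding from the point farthest from its
    centroid. Inertia is verified to be non-increasing across iterations.
    """
    n = points.shape[0]
    centroids = _init_centroids(points, k, rng, init)
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        if inertia > prev_inertia + 1e-9 * max(1.0, prev_inertia):
            raise AssertionError("Lloyd iteration increased inertia")
        for c in range(k):
            mask = labels == c
            if mask.any():
                centroids[c] = points[mask].mean(axis=0)
            else:  # repair: reseed from the farthest point
                far = d2[np.arange(n), labels].argmax()
                centroids[c] = points[far]
                labels[far] = c
        if prev_inertia - inertia <= 1e-12 * max(1.0, inertia):
            prev_inertia = inertia
            break
        prev_inertia = inertia
    # final assignment against the last centroids
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    for c in range(k):
        if not np.any(labels == c):
            far = d2[np.arange(n), labels].argmax()
            centroids[c] = points[far]
            labels[far] = c
    return labels, centroids, inertia


def kmeans_fit(
    data: FeatureTable | np.ndarray,
    k: int,
    n_iter: int = 200,
    n_restarts: int = 10,
    seed: int = 0,
    feature_ids: list[str] | None = None,
    init: str = "kmeans++",
) -> ClusterModel:
    """Best-of-restarts K-means on features as points in sample space.

    `init='kmeans++'` (default) spreads the seeded initial centroids by
    D^2-sampling; `init='random'` picks uniform random points.
    """
    if isinstance(data, FeatureTable):
        points = data.values.T
        feature_ids = list(data.feature_ids)
    else:
        points = np.asarray(data, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(points.shape[0])]
    if k >= points.shape[0]:
        raise ValueError(f"K={k} must be smaller than the number of features")
    if k < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, centroids, inertia = _lloyd(points, k, n_iter, rng, init)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    return ClusterModel(k, feature_ids, labels, centroids, inertia, seed)


@dataclass
class KSelectionTable:
    table: pd.DataFrame  # columns: k, inertia, silhouette, davies_bouldin

    def __post_init__(self) -> None:
        need = {"k", "inertia", "silhouette", "davies_bouldin"}
        if not need <= set(self.table.columns):
            raise ValueError(f"K-selection table must have columns {sorted(need)}")


def select_k(
    data: FeatureTable | np.ndarray,
    k_min: int = 2,
    k_max: int = 100,
    n_iter: int = 200,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[int, KSelectionTable]:
    """Fit K-means over [k_min, k_max]; choose K by best mean rank of
    silhouette (descending) and Davies-Bouldin (ascending), smaller K on ties.

    Inertia is reported for elbow inspection only (it has no intrinsic
    optimum in K).
    """
    points = data.values.T if isinstance(data, FeatureTable) else np.asarray(data, float)
    n = points.shape[0]
    if k_max >= n:
        log.warning("k_max=%d capped to %d (need K < #features)", k_max, n - 1)
        k_max = n - 1
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"empty K range [{k_min}, {k_max}]")

    dist = squareform(pdist(points))
    rows = []
    models = {}
    rng = np.random.default_rng(seed)
    for k in range(k_min, k_max + 1):
        model = kmeans_fit(points, k, n_iter, n_restarts, int(rng.integers(2**31)))
        sil = float(silhouette_score(dist, model.labels, metric="precomputed"))
        db = float(davies_bouldin_score(points, model.labels))
        rows.append({"k": k, "inertia": model.inertia, "silhouette": sil, "davies_bouldin": db})
        models[k] = model
    table = pd.DataFrame(rows)
    rank_sil = table["silhouette"].rank(ascending=False, method="average")
    rank_db = table["davies_bouldin"].rank(ascending=True, method="average")
    mean_rank = (rank_sil + rank_db) / 2.0
    best_k = int(table.loc[mean_rank.idxmin(), "k"])  # idxmin takes first on ties
    return best_k, KSelectionTable(table)


def homogeneity_scores(
    model: ClusterModel, features: FeatureTable, singleton: str = "one"
) -> dict[int, float]:
    """Mean pairwise Spearman correlation among each cluster's members.

    Singleton clusters are trivially homogeneous (h = 1) by default;
    `singleton='exclude'` marks them NaN so they never qualify.
    """
    if singleton not in ("one", "exclude"):
        raise ValueError("singleton must be 'one' or 'exclude'")
    pos = {f: i for i, f in enumerate(features.feature_ids)}
    ranks = sps.rankdata(features.values, method="average", axis=0)
    scores: dict[int, float] = {}
    for c in range(model.k):
        members = model.members(c)
        if len(members) == 0:
            continue
        if len(members) == 1:
            scores[c] = 1.0 if singleton == "one" else np.nan
            continue
        sub = ranks[:, [pos[f] for f in members]]
        corr = np.corrcoef(sub, rowvar=False)
        iu = np.triu_indices(len(members), k=1)
        scores[c] = float(corr[iu].mean())
    return scores


@dataclass
class ClusterSummary:
    cluster_id: int
    members: list[str]
    homogeneity: float
    representative: str | None


@dataclass
class MetaRadiomicsSignature:
    clusters: list[ClusterSummary]
    threshold: float
    sample_ids: list[str]
    meta_feature_ids: list[str] = field(default_factory=list)
    meta_values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def n_meta_features(self) -> int:
        return len(self.meta_feature_ids)

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "n_members": [len(c.members) for c in self.clusters],
                "homogeneity": [c.homogeneity for c in self.clusters],
                "representative": [c.representative or "" for c in self.clusters],
                "members": [";".join(c.members) for c in self.clusters],
            }
        )

    def meta_table(self) -> FeatureTable:
        return FeatureTable(list(self.sample_ids), list(self.meta_feature_ids), self.meta_values.T)


def extract_meta_features(
    model: ClusterModel,
    h: dict[int, float],
    features: FeatureTable,
    threshold: float = 0.75,
    seed: int = 0,
) -> MetaRadiomicsSignature:
    """Representative (meta-radiomic) feature per qualifying cluster.

    A cluster qualifies when h > threshold; its representative is the member
    nearest the centroid in standardized space, exact distance ties broken by
    a seeded uniform choice.
    """
    rng = np.random.default_rng(seed)
    pos = {f: i for i, f in enumerate(features.feature_ids)}
    summaries: list[ClusterSummary] = []
    meta_ids: list[str] = []
    meta_rows: list[np.ndarray] = []
    for c in range(model.k):
        members = model.members(c)
        if not members:
            continue
        score = h.get(c, np.nan)
        rep = None
        if np.isfinite(score) and score > threshold:
            pts = features.values[:, [pos[f] for f in members]].T
            d2 = ((pts - model.centroids[c][None, :]) ** 2).sum(axis=1)
            ties = np.nonzero(d2 == d2.min())[0]
            rep = members[int(rng.choice(ties))]
            meta_ids.append(rep)
            meta_rows.append(features.values[:, pos[rep]])
        summaries.append(ClusterSummary(c, members, score, rep))
    if not meta_ids:
        log.warning("no cluster passed the homogeneity threshold %.2f", threshold)
    meta_values = (
        np.vstack(meta_rows) if meta_rows else np.empty((0, features.n_samples))
    )
    return MetaRadiomicsSignature(
        summaries, threshold, list(features.sample_ids), meta_ids, meta_values
    )


def pca_project(data: FeatureTable | np.ndarray, n_components: int = 2):
    """Mean-centered projection of feature points onto top principal axes.

    Returns (coordinates: n_features x n_components, explained_variance).
    """
    points = data.values.T if isinstance(data, FeatureTable) else np.asarray(data, float)
    if points.shape[0] < 2 or points.shape[1] < 2:
        raise ValueError("PCA needs at least 2 features and 2 dimensions")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(points)
    return coords, pca.explained_variance_
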