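"""Evaluation and application suite for texture feature volumes.

Implements the standard evaluation battery for frozen texture features:

* PCA reduction fitted on a seeded random voxel subset (component maps,
  explained-variance ratios);
* in-plane Gaussian smoothing of feature maps;
* two-step clustering — k-means with 128 centroids on a seeded subsample,
  nearest-centroid assignment of all voxels, then Ward/Euclidean
  agglomeration of the centroids into a dendrogram that can be cut at any
  number of clusters, with silhouette scores per cut;
* cross-section consistency as the mean IoU of cluster assignments between
  adjacent sections;
* linear probing — one-vs-rest logistic regression with class-balanced
  training subsets, macro F1 mean and standard error over repeated fits;
* ridge regression of morphological measures (cortical depth, white-matter
  depth, curvature, obliqueness) from z-scored features, scored by R^2 on a
  disjoint test set;
* query-based retrieval via a Gaussian RBF affinity to the mean feature of a
  set of query voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import f1_score, pairwise_distances_argmin, silhouette_score
from sklearn.multiclass import OneVsRestClassifier

from .contrastive import FeatureMap

__all__ = [
    "ClusterResult",
    "ProbeResult",
    "pca_reduce",
    "smooth_feature_map",
    "two_step_cluster",
    "cross_section_iou",
    "linear_probe",
    "morphology_regression",
    "rbf_retrieval",
]


def pca_reduce(
    features: np.ndarray,
    n_components: int,
    subset: int = 1_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Project features onto principal components fitted on a random subset.

    ``features`` is (n_samples, d); components are fitted on at most
    ``subset`` seeded random rows and applied to all rows.  Returns the
    reduced features, the (non-increasing) explained-variance ratios, and the
    fitted projector.
    """
    features = np.asarray(features)
    if n_components > features.shape[1]:
        raise ValueError("n_components exceeds the feature dimension")
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    fit_rows = features if n <= subset else features[rng.choice(n, size=subset, replace=False)]
    pca = PCA(n_components=n_components, random_state=int(rng.integers(2**31)))
    pca.fit(fit_rows)
    return pca.transform(features), pca.explained_variance_ratio_, pca


def smooth_feature_map(fm: FeatureMap, sigma: float) -> FeatureMap:
    """Channel-wise in-plane Gaussian smoothing (sigma in grid units)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        feats = fm.features.copy()
    else:
        feats = ndimage.gaussian_filter(fm.features, sigma=(sigma, sigma, 0), mode="reflect")
    return FeatureMap(feats, fm.tile_px, fm.stride_px, fm.section, fm.pixel_size_um, fm.tile_labels)


@dataclass
class ClusterResult:
    """Two-step clustering output: k-means centroids plus their Ward tree."""

    kmeans_centroids: np.ndarray
    assignments: np.ndarray  # per-sample centroid index
    linkage_matrix: np.ndarray
    subset_indices: np.ndarray
    silhouette_curve: dict[int, float] = dataclass_field(default_factory=dict)
    _features_subset: np.ndarray | None = None

    @property
    def n_centroids(self) -> int:
        return len(self.kmeans_centroids)

    def centroid_labels(self, n_clusters: int) -> np.ndarray:
        """Merged-cluster label of each k-means centroid at a dendrogram cut."""
        if n_clusters < 1 or n_clusters > self.n_centroids:
            raise ValueError("cut outside [1, n_centroids]")
        if n_clusters == self.n_centroids:
            return np.arange(self.n_centroids)
        return fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust") - 1

    def cut_labels(self, n_clusters: int) -> np.ndarray:
        """Per-sample labels at a cut of the centroid dendrogram."""
        return self.centroid_labels(n_clusters)[self.assignments]

    def silhouette(self, n_clusters: int) -> float:
        """Silhouette on the k-means subsample under the merged labels.

        Returns NaN for a single cluster (score undefined).
        """
        if n_clusters in self.silhouette_curve:
            return self.silhouette_curve[n_clusters]
        labels = self.cut_labels(n_clusters)[self.subset_indices]
        if len(np.unique(labels)) < 2:
            score = float("nan")
        else:
            score = float(silhouette_score(self._features_subset, labels))
        self.silhouette_curve[n_clusters] = score
        return score


def two_step_cluster(
    features: np.ndarray,
    k: int = 128,
    subset: int = 100_000,
    seed: int = 0,
) -> ClusterResult:
    """K-means on a seeded subsample followed by Ward agglomeration of centroids."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k > min(n, subset):
        raise ValueError("k exceeds the number of available samples")
    rng = np.random.default_rng(seed)
    idx = np.arange(n) if n <= subset else np.sort(rng.choice(n, size=subset, replace=False))
    km = KMeans(n_clusters=k, random_state=int(rng.integers(2**31)), n_init=3)
    km.fit(features[idx])
    assignments = pairwise_distances_argmin(features, km.cluster_centers_)
    link = linkage(km.cluster_centers_, method="ward", metric="euclidean")
    return ClusterResult(
        kmeans_centroids=km.cluster_centers_,
        assignments=assignments,
        linkage_matrix=link,
        subset_indices=idx,
        _features_subset=features[idx],
    )


def cross_section_iou(
    assignments: np.ndarray,
    foreground: np.ndarray | None = None,
) -> float:
    """Mean IoU of cluster assignments between neighboring sections.

    ``assignments`` is an (S, ...) integer label volume.  For each adjacent
    section pair and each cluster present in the union of their foregrounds,
    IoU = |A and B| / |A or B| is computed on foreground voxels; scores are
    averaged over clusters, then over pairs.
    """
    assignments = np.asarray(assignments)
    if assignments.shape[0] < 2:
        raise ValueError("need at least two sections")
    if foreground is None:
        foreground = np.ones(assignments.shape, dtype=bool)
    pair_means = []
    for s in range(assignments.shape[0] - 1):
        fg = foreground[s] & foreground[s + 1]
        if not fg.any():
            raise ValueError(f"no foreground overlap between sections {s} and {s + 1}")
        a = assignments[s][fg]
        b = assignments[s + 1][fg]
        ious = []
        for c in np.union1d(a, b):
            inter = np.count_nonzero((a == c) & (b == c))
            union = np.count_nonzero((a == c) | (b == c))
            ious.append(inter / union)
        pair_means.append(np.mean(ious))
    return float(np.mean(pair_means))


@dataclass
class ProbeResult:
    """Macro-F1 of a linear probe versus the number of labels per class."""

    n_per_class: np.ndarray
    f1_mean: np.ndarray
    f1_se: np.ndarray
    repeats: int


def linear_probe(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    n_per_class: list[int],
    repeats: int = 50,
    seed: int = 0,
    max_iter: int = 1000,
) -> ProbeResult:
    """One-vs-rest logistic regression on class-balanced label subsets.

    For each label budget, the probe is refit ``repeats`` times on seeded
    random class-balanced subsets of the training features and scored by
    macro F1 on the held-out test set; the mean and standard error over
    refits are reported.
    """
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    means, ses = [], []
    for n in n_per_class:
        scores = []
        for _ in range(repeats):
            rows = []
            for c in classes:
                pool = np.flatnonzero(train_labels == c)
                if len(pool) < n:
                    raise ValueError(f"class {c} has fewer than {n} training samples")
                rows.append(rng.choice(pool, size=n, replace=False))
            rows = np.concatenate(rows)
            mean = train_features[rows].mean(axis=0)
            std = train_features[rows].std(axis=0)
            std[std == 0] = 1.0
            clf = OneVsRestClassifier(
                LogisticRegression(max_iter=max_iter, random_state=int(rng.integers(2**31)))
            )
            clf.fit((train_features[rows] - mean) / std, train_labels[rows])
            pred = clf.predict((test_features - mean) / std)
            scores.append(f1_score(test_labels, pred, average="macro"))
        scores = np.asarray(scores)
        means.append(scores.mean())
        ses.append(scores.std(ddof=1) / np.sqrt(repeats) if repeats > 1 else 0.0)
    return ProbeResult(np.asarray(n_per_class), np.asarray(means), np.asarray(ses), repeats)


def morphology_regression(
    train_features: np.ndarray,
    train_targets: dict[str, np.ndarray],
    test_features: np.ndarray,
    test_targets: dict[str, np.ndarray],
    l2: float = 1e4,
    n_train: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Ridge regression of morphological measures from z-scored features.

    Features are standardized with statistics of the (seeded, subsampled)
    training split; one ridge model per target; scores are R^2 on the test
    split.  Targets with NaNs (outside their anatomical domain) are filtered
    per target.
    """
    rng = np.random.default_rng(seed)
    results: dict[str, float] = {}
    for name, y_train in train_targets.items():
        y_test = test_targets[name]
        keep_tr = np.isfinite(y_train)
        keep_te = np.isfinite(y_test)
        x_tr, y_tr = train_features[keep_tr], y_train[keep_tr]
        if y_tr.size == 0 or np.var(y_tr) == 0:
            raise ValueError(f"target {name!r} has zero variance on the training split")
        if len(y_tr) > n_train:
            rows = rng.choice(len(y_tr), size=n_train, replace=False)
            x_tr, y_tr = x_tr[rows], y_tr[rows]
        mean = x_tr.mean(axis=0)
        std = x_tr.std(axis=0)
        std[std == 0] = 1.0
        model = Ridge(alpha=l2)
        model.fit((x_tr - mean) / std, y_tr)
        x_te = (test_features[keep_te] - mean) / std
        y_hat = model.predict(x_te)
        ss_res = np.sum((y_test[keep_te] - y_hat) ** 2)
        ss_tot = np.sum((y_test[keep_te] - y_test[keep_te].mean()) ** 2)
        results[name] = float(1.0 - ss_res / ss_tot)
    return results


def rbf_retrieval(
    features: np.ndarray,
    query_indices: np.ndarray,
    sigma: float = 3.5,
) -> np.ndarray:
    """Gaussian RBF affinity of every voxel to the mean query feature.

    ``features`` is (n_voxels, d) (typically PCA-reduced and smoothed);
    ``query_indices`` selects the example voxels.  The affinity is
    ``exp(-||h - q||^2 / (2 sigma^2))`` with ``q`` the query mean, so a
    single-query search has affinity exactly 1 at its own voxel.
    """
    query_indices = np.atleast_1d(np.asarray(query_indices))
    if query_indices.size == 0:
        raise ValueError("need at least one query location")
    q = np.asarray(features)[query_indices].mean(axis=0)
    d2 = ((features - q) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))
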