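"""Latent-space K-means prediction of unlabelled sequences.

The prediction phase clusters the latent representations of unlabelled
sequences into c = 2 groups with a bespoke Lloyd iteration (assign each
point to its nearest centroid, recompute centroids as cluster means, repeat
to a fixpoint), then maps each cluster to the class whose labelled-training
latent mean lies nearest its centroid.  Test labels are never consulted, so
the prediction stays honestly semi-supervised.

Comparator predictors (random forest / support-vector / decision-tree,
trained on the labelled latents) are thin adapters over scikit-learn and
are not part of the clustering contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


def _pairwise_sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (n_points, n_centroids)."""
    # (x - c)^2 expansion; clip tiny negatives from cancellation
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ C.T
        + np.sum(C * C, axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _farthest_point_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding: random first centre, then repeatedly
    the point farthest from its nearest chosen centre."""
    n = X.shape[0]
    centers = [int(rng.integers(n))]
    min_d2 = _pairwise_sq_dists(X, X[centers])[:, 0]
    while len(centers) < c:
        centers.append(int(np.argmax(min_d2)))
        min_d2 = np.minimum(min_d2, _pairwise_sq_dists(X, X[centers[-1:]])[:, 0])
    return X[centers].copy()


class LatentKMeans(ClusterMixin, BaseEstimator):
    """Lloyd K-means with farthest-point seeding and restarts.

    Ties in the nearest-centroid assignment break to the lowest cluster
    index; an emptied cluster is reseeded at the point farthest from its
    assigned centroid.  The first restart seeds centroids by greedy
    farthest-point, later restarts by uniform distinct points; the best run
    by inertia (total within-cluster squared Euclidean distance) is kept.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (n_clusters, d) centroid matrix.
    labels_ : per-point cluster index of the training data.
    inertia_ : within-cluster sum of squared distances.
    n_iter_ : Lloyd iterations used by the winning restart.
    inertia_history_ : per-iteration inertia of the winning restart
        (non-increasing).
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 10, max_iter: int = 300,
                 tol: float = 1e-4, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, rng: np.random.Generator, restart: int):
        c = self.n_clusters
        if restart == 0:
            centers = _farthest_point_init(X, c, rng)
        else:
            # uniform distinct-point seeding: reaches Lloyd basins (e.g.
            # singleton-cluster optima) that greedy farthest-point cannot
            centers = X[rng.choice(X.shape[0], size=c, replace=False)].copy()
        assign = np.full(X.shape[0], -1, dtype=np.int64)
        history: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2 = _pairwise_sq_dists(X, centers)
            new_assign = np.argmin(d2, axis=1)  # argmin ties -> lowest index
            # empty-cluster repair: reseed at the point farthest from its centroid
            for b in range(c):
                if not np.any(new_assign == b):
                    worst = int(np.argmax(d2[np.arange(len(X)), new_assign]))
                    new_assign[worst] = b
                    centers[b] = X[worst]
            history.append(float(d2[np.arange(len(X)), new_assign].sum()))
            new_centers = np.vstack(
                [X[new_assign == b].mean(axis=0) for b in range(c)]
            )
            shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
            converged = np.array_equal(new_assign, assign) or shift < self.tol
            centers, assign = new_centers, new_assign
            if converged:
                break
        d2 = _pairwise_sq_dists(X, centers)
        assign = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(len(X)), assign].sum())
        history.append(inertia)
        return centers, assign, inertia, n_iter, history

    def fit(self, X, y=None) -> "LatentKMeans":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"{X.shape[0]} points cannot form {self.n_clusters} clusters"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(max(1, self.n_restarts)):
            result = self._lloyd(X, rng, restart)
            if best is None or result[2] < best[2]:
                best = result
        centers, assign, inertia, n_iter, history = best
        self.cluster_centers_ = centers
        self.labels_ = assign
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.inertia_history_ = history
        return self

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid assignment; ties break to the lowest cluster index."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"expected points of dimension {self.cluster_centers_.shape[1]}"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=np.int64)
        return np.argmin(_pairwise_sq_dists(X, self.cluster_centers_), axis=1)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        return np.sqrt(_pairwise_sq_dists(np.asarray(X, dtype=np.float64),
                                          self.cluster_centers_))

    def save(self, path: Union[str, Path], label_map: "ClusterLabelMap" = None) -> None:
        check_is_fitted(self, "cluster_centers_")
        payload = {
            "n_clusters": self.n_clusters,
            "random_state": self.random_state,
            "inertia": self.inertia_,
            "cluster_centers": self.cluster_centers_.tolist(),
        }
        if label_map is not None:
            payload["label_map"] = {str(k): int(v) for k, v in label_map.mapping.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]):
        payload = json.loads(Path(path).read_text())
        model = cls(n_clusters=payload["n_clusters"], random_state=payload["random_state"])
        model.cluster_centers_ = np.asarray(payload["cluster_centers"], dtype=np.float64)
        model.inertia_ = payload["inertia"]
        label_map = None
        if "label_map" in payload:
            label_map = ClusterLabelMap(
                {int(k): int(v) for k, v in payload["label_map"].items()}
            )
        return model, label_map


def kmeans_fit(X, c: int = 2, seed: int = 0, tol: float = 1e-4, max_iter: int = 300,
               n_restarts: int = 10) -> LatentKMeans:
    """Functional wrapper over :class:`LatentKMeans`."""
    return LatentKMeans(
        n_clusters=c, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(X)


def kmeans_assign(model: LatentKMeans, X) -> np.ndarray:
    return model.predict(X)


@dataclass
class ClusterLabelMap:
    """Cluster index -> class label; a bijection for the two-cluster case."""

    mapping: dict[int, int]

    def __getitem__(self, cluster: int) -> int:
        return self.mapping[int(cluster)]


def map_clusters_to_labels(model: LatentKMeans, labelled_latents, labels) -> ClusterLabelMap:
    """Assign each cluster the class whose labelled-latent mean is nearest.

    Uses only the labelled training latents, never test labels.  If both
    clusters prefer the same class, the identity and swap maps are scored by
    agreement with the labelled data and the better one wins; an exact tie
    gives the identity map.
    """
    X = np.asarray(labelled_latents, dtype=np.float64)
    y = np.asarray(labels)
    present = sorted(set(int(v) for v in y))
    if present != [0, 1]:
        raise ValueError(f"both classes must be present in labels, got {present}")
    class_means = np.vstack([X[y == cls].mean(axis=0) for cls in (0, 1)])
    d2 = _pairwise_sq_dists(model.cluster_centers_, class_means)  # (c, 2)
    preferred = np.argmin(d2, axis=1)
    if model.n_clusters == 2 and len(set(preferred.tolist())) < 2:
        # degenerate geometry: pick the bijection agreeing best with the
        # labelled data
        clusters = model.predict(X)
        scores = []
        for mapping in ({0: 0, 1: 1}, {0: 1, 1: 0}):
            pred = np.array([mapping[int(b)] for b in clusters])
            scores.append(float(np.mean(pred == y)))
        mapping = {0: 0, 1: 1} if scores[0] >= scores[1] else {0: 1, 1: 0}
        return ClusterLabelMap(mapping)
    return ClusterLabelMap({b: int(cls) for b, cls in enumerate(preferred)})


def predict_labels(model: LatentKMeans, label_map: ClusterLabelMap, X) -> np.ndarray:
    """Composition of nearest-centroid assignment and the cluster->label map."""
    clusters = model.predict(X)
    if clusters.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.array([label_map[int(b)] for b in clusters], dtype=np.int64)


def make_comparator(kind: str, seed: int = 0):
    """Supervised comparator predictors over the labelled latents.

    Thin adapters over scikit-learn (non-bespoke): ``rf`` random-forest
    regression, ``svr`` support-vector regression (both thresholded at 0.5),
    ``tree`` decision-tree classifier.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeClassifier

    if kind == "rf":
        return _ThresholdedRegressor(RandomForestRegressor(random_state=seed))
    if kind == "svr":
        return _ThresholdedRegressor(SVR())
    if kind == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown comparator {kind!r}")


class _ThresholdedRegressor:
    """Regression on 0/1 targets, thresholded at 0.5 for class output."""

    def __init__(self, base):
        self.base = base

    def fit(self, X, y):
        self.base.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        return (self.base.predict(X) >= 0.5).astype(np.int64)
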