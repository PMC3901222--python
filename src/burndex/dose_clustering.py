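"""K-means clustering of dose-response profiles with tandem k selection.

The number of clusters is chosen by combining the elbow in the within-cluster
error with silhouette separation: the scan records, for each k, the best of
``replicates`` seeded k-means restarts, and the chosen k is the smallest one
whose mean silhouette is a local maximum and beyond which no scanned k offers
a relative silhouette gain above ``silhouette_gain_threshold``.

K-means restarts are initialized from distinct randomly chosen profiles (the
classical Lloyd setup, no ++-style seeding); an emptied cluster is re-seeded
from the point farthest from its current centroid.  The within-cluster error
is the k-means objective (sum of squared Euclidean point-to-centroid
distances) by default; an unsquared sum is available since the source
analysis did not state which it plotted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_samples

from .cohort_data import VariableKey
from .preprocess import DoseResponseProfile

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    k_min: int = 2
    k_max: int = 8
    replicates: int = 10
    seed: int = 0
    silhouette_gain_threshold: float = 0.05
    squared_within: bool = True
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class ClusteringResult:
    k: int
    keys: list[VariableKey]
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float
    silhouettes: np.ndarray | None
    mean_silhouette: float | None

    @property
    def assignment(self) -> dict[VariableKey, int]:
        return {key: int(lab) for key, lab in zip(self.keys, self.labels)}

    def silhouette_by_key(self) -> dict[VariableKey, float] | None:
        if self.silhouettes is None:
            return None
        return {key: float(s) for key, s in zip(self.keys, self.silhouettes)}


def _profile_matrix(profiles: Sequence[DoseResponseProfile]) -> tuple[list[VariableKey], np.ndarray]:
    keys = [p.variable for p in profiles]
    X = np.vstack([p.normalized for p in profiles])
    return keys, X


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """One k-means run from k distinct random profiles; returns (labels, centroids)."""
    centroids = X[rng.choice(len(X), size=k, replace=False)].copy()
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        new_labels = d2.argmin(1)
        for j in range(k):
            members = new_labels == j
            if members.any():
                centroids[j] = X[members].mean(0)
            else:
                # re-seed an emptied cluster from the farthest point
                far = d2[np.arange(len(X)), new_labels].argmax()
                centroids[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, centroids


def _within_ss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray, squared: bool) -> float:
    d = np.linalg.norm(X - centroids[labels], axis=1)
    return float((d**2).sum() if squared else d.sum())


def kmeans_profiles(
    profiles: Sequence[DoseResponseProfile],
    k: int,
    config: ClusterConfig | None = None,
) -> ClusteringResult:
    """Best of ``replicates`` seeded k-means restarts at a fixed k.

    Deterministic given ``config.seed``.  ``k=1`` degenerates to a single
    cluster whose centroid is the coordinate-wise mean; the silhouette is
    then not applicable and reported as None.
    """
    config = config or ClusterConfig()
    keys, X = _profile_matrix(profiles)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")
    if k == 1:
        centroids = X.mean(0, keepdims=True)
        labels = np.zeros(len(X), int)
        return ClusteringResult(
            1, keys, labels, centroids,
            _within_ss(X, labels, centroids, config.squared_within), None, None,
        )
    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(config.replicates):
        labels, centroids = _lloyd(X, k, rng, config.max_iter)
        wss = _within_ss(X, labels, centroids, config.squared_within)
        if best is None or wss < best[0] - 1e-12:
            best = (wss, labels, centroids)
    wss, labels, centroids = best
    sil = silhouette_values_from_labels(X, labels)
    return ClusteringResult(
        k, keys, labels, centroids, wss, sil, float(sil.mean())
    )


def silhouette_values_from_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Euclidean silhouette per point; singleton clusters score 0."""
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    return silhouette_samples(X, labels, metric="euclidean")


def silhouette_values(
    profiles: Sequence[DoseResponseProfile],
    assignment: Mapping[VariableKey, int],
) -> dict[VariableKey, float]:
    """Silhouette of each profile under an externally given assignment."""
    keys, X = _profile_matrix(profiles)
    labels = np.array([assignment[k] for k in keys])
    vals = silhouette_values_from_labels(X, labels)
    return {k: float(s) for k, s in zip(keys, vals)}


@dataclass
class KScan:
    """Per-k quality of the best restart: within-cluster error and silhouette."""

    within_ss: dict[int, float] = field(default_factory=dict)
    mean_silhouette: dict[int, float] = field(default_factory=dict)
    results: dict[int, ClusteringResult] = field(default_factory=dict)

    def relative_gain(self, k_from: int, k_to: int) -> float:
        """Relative change in mean silhouette between two scanned k."""
        s0 = self.mean_silhouette[k_from]
        return (self.mean_silhouette[k_to] - s0) / s0


def scan_k(
    profiles: Sequence[DoseResponseProfile],
    config: ClusterConfig | None = None,
) -> KScan:
    """Cluster at every k in the configured range; keep the best restart per k."""
    config = config or ClusterConfig()
    scan = KScan()
    prev = np.inf
    for k in config.k_range:
        res = kmeans_profiles(profiles, k, config)
        if res.within_ss > prev + 1e-9:
            logger.warning(
                "within-cluster error rose from k=%d to k=%d "
                "(restart count too small for a clean elbow)", k - 1, k
            )
        prev = res.within_ss
        scan.within_ss[k] = res.within_ss
        scan.mean_silhouette[k] = res.mean_silhouette
        scan.results[k] = res
    return scan


def choose_k(scan: KScan, gain_threshold: float = 0.05) -> int:
    """Tandem elbow/silhouette selection of the number of clusters.

    Returns the smallest k whose mean silhouette is a local maximum of the
    scan and for which the best relative silhouette gain available at any
    larger scanned k stays below ``gain_threshold``; ties break to the
    smaller k.  With no qualifying local maximum the silhouette argmax is
    returned with a warning.
    """
    ks = sorted(scan.mean_silhouette)
    if len(ks) < 3:
        raise ValueError("scan must cover at least three k values")
    sil = scan.mean_silhouette
    for i, k in enumerate(ks):
        left_ok = i == 0 or sil[k] >= sil[ks[i - 1]]
        right_ok = i == len(ks) - 1 or sil[k] >= sil[ks[i + 1]]
        if not (left_ok and right_ok):
            continue
        larger = ks[i + 1:]
        if not larger or max(scan.relative_gain(k, kk) for kk in larger) < gain_threshold:
            return k
    best = max(ks, key=lambda k: sil[k])
    logger.warning(
        "no local silhouette maximum met the gain rule; falling back to argmax k=%d", best
    )
    return best
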