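"""First-pass k-means tissue clustering and cross-subject harmonization.

Each subject's z-scored channel stack is partitioned into k = 6 intensity
clusters (squared-Euclidean k-means, many k-means++ replicates, best
inertia kept).  Cluster numbering is arbitrary per subject, so every
subject's centroids are matched to a designated reference subject by an
optimal one-to-one assignment before any cross-subject averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .extract import ChannelStack
from .image import VolumetricImage

__all__ = [
    "ClusterModel",
    "kmeans_firstpass",
    "match_centroids",
    "labels_to_binary_maps",
    "silhouette_values",
]

DEFAULT_K = 6
DEFAULT_MAX_ITER = 1000
DEFAULT_REPLICATES = 100
SILHOUETTE_SUBSAMPLE = 200_000


@dataclass
class ClusterModel:
    """k-means result in z-score space; labels are 1..k."""

    k: int
    centroids: np.ndarray  # (k, n_channels)
    labels: np.ndarray  # (n,), values 1..k
    distances: np.ndarray  # (n,), Euclidean distance to own centroid
    inertia: float
    silhouettes: np.ndarray | None = None

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def kmeans_firstpass(
    stack: ChannelStack,
    k: int = DEFAULT_K,
    max_iter: int = DEFAULT_MAX_ITER,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-``replicates`` Lloyd k-means on the z-scored channels.

    k-means++ initialization, squared-Euclidean objective; deterministic
    given ``seed``.  The solver relocates empty clusters internally, so the
    returned model always has k nonempty clusters.
    """
    if stack.zscores is None:
        raise ValueError("stack must be standardized before clustering")
    x = stack.zscores
    if len(stack) < 50 * k:
        raise ValueError(f"{len(stack)} voxels cannot support {k} clusters (need >= {50 * k})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=replicates,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=int(seed) % (2**31),
    ).fit(x)
    labels = km.labels_.astype(np.int16) + 1
    dist = np.linalg.norm(x - km.cluster_centers_[km.labels_], axis=1)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        distances=dist,
        inertia=float(km.inertia_),
    )


def match_centroids(subject: ClusterModel, reference: ClusterModel) -> ClusterModel:
    """Renumber the subject's clusters to the reference's ordering.

    Solves the assignment problem minimizing the total Euclidean distance
    between subject and reference centroids (Hungarian algorithm) and
    permutes centroids/labels accordingly.
    """
    if subject.k != reference.k:
        raise ValueError("cluster counts differ")
    cost = np.linalg.norm(
        subject.centroids[:, None, :] - reference.centroids[None, :, :], axis=2
    )
    row, col = linear_sum_assignment(cost)
    # subject cluster row[i] becomes reference index col[i]
    new_index = np.empty(subject.k, dtype=int)  # old -> new
    new_index[row] = col
    centroids = np.empty_like(subject.centroids)
    centroids[new_index] = subject.centroids
    labels = (new_index[subject.labels - 1] + 1).astype(subject.labels.dtype)
    sil = subject.silhouettes  # per-voxel, unaffected by renumbering
    return replace(subject, centroids=centroids, labels=labels, silhouettes=sil)


def labels_to_binary_maps(model: ClusterModel, stack: ChannelStack) -> list[VolumetricImage]:
    """One binary volume per cluster; together they partition the tissue mask."""
    maps = []
    for c in range(1, model.k + 1):
        maps.append(stack.volume_from((model.labels == c).astype(float)))
    return maps


def silhouette_values(
    stack: ChannelStack, model: ClusterModel, seed: int = 0
) -> np.ndarray:
    """Classical per-voxel silhouette s = (b - a) / max(a, b) in z-space.

    Above ``SILHOUETTE_SUBSAMPLE`` voxels, a seeded subsample is scored and
    the remaining voxels get the mean silhouette of their cluster (the
    index downstream only uses per-cluster aggregates).  Singleton-cluster
    voxels score 0 by convention.
    """
    if model.k < 2:
        raise ValueError("silhouettes require k >= 2")
    x = stack.zscores
    n = len(stack)
    if n <= SILHOUETTE_SUBSAMPLE:
        return silhouette_samples(x, model.labels)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=SILHOUETTE_SUBSAMPLE, replace=False)
    sub = silhouette_samples(x[idx], model.labels[idx])
    out = np.empty(n)
    for c in range(1, model.k + 1):
        sel = model.labels[idx] == c
        out[model.labels == c] = float(sub[sel].mean()) if sel.any() else 0.0
    out[idx] = sub
    return out
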