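"""Prior-informed refinement of the binary first-pass segmentation.

Each voxel's intensity-based cluster assignment is checked against the
spatial priors projected into subject space.  An inconsistent voxel (the
prior argmax names a different cluster) is reassigned to that alternate
cluster only if the evidence is strong: alternate prior >= 0.75, or the
alternate exceeds the original cluster's prior by >= 0.20.  The surviving
binary labels are then converted to probabilities by multiplying each
voxel's prior with a standardized centroid-distance weight, so confidence
falls off both with spatial atypicality and with distance from the cluster
centroid in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterModel
from .extract import ChannelStack
from .image import VolumetricImage

__all__ = [
    "SegmentationResult",
    "standardize_distances",
    "reassign_inconsistent",
    "finalize_probabilistic",
    "refine_subject",
]

P_HIGH = 0.75
P_MARGIN = 0.20


@dataclass
class SegmentationResult:
    """Final probabilistic segmentation for one subject."""

    final_probs: list  # six VolumetricImage in [0, 1]
    final_labels: VolumetricImage  # int volume, 1..6 inside mask, 0 outside
    reassigned_mask: VolumetricImage  # 1 where the label changed
    distance_weights: VolumetricImage  # standardized weights in [0, 1]


def standardize_distances(model: ClusterModel, labels: np.ndarray | None = None) -> np.ndarray:
    """Per-cluster min-max rescaling of centroid distances to [0, 1].

    Within each cluster, w = 1 - (d - d_min) / (d_max - d_min): the voxel
    nearest its centroid weighs 1, the farthest 0.  A degenerate cluster
    (all distances equal) weighs 1 throughout.
    """
    labels = model.labels if labels is None else labels
    w = np.zeros_like(model.distances, dtype=float)
    for c in range(1, model.k + 1):
        sel = labels == c
        if not sel.any():
            continue
        d = model.distances[sel]
        d_min, d_max = float(d.min()), float(d.max())
        w[sel] = 1.0 if d_max == d_min else 1.0 - (d - d_min) / (d_max - d_min)
    return w


def reassign_inconsistent(
    labels: np.ndarray,
    priors_at_voxels: np.ndarray,
    p_high: float = P_HIGH,
    p_margin: float = P_MARGIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Move voxels to the prior-argmax cluster when the prior evidence is strong.

    ``priors_at_voxels`` is (n, 6): the subject-space prior of each cluster
    at each masked voxel.  A voxel whose label already matches the argmax
    is consistent and untouched.  Otherwise it moves to the alternate
    cluster iff prior_alt >= p_high OR prior_alt - prior_label >= p_margin.
    Argmax ties break toward the lower cluster index.

    Returns (new labels, boolean reassigned mask).
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    alternate = np.argmax(priors_at_voxels, axis=1) + 1  # ties -> lower index
    idx = np.arange(n)
    p_alt = priors_at_voxels[idx, alternate - 1]
    p_orig = priors_at_voxels[idx, labels - 1]
    inconsistent = alternate != labels
    move = inconsistent & ((p_alt >= p_high) | (p_alt - p_orig >= p_margin))
    new_labels = np.where(move, alternate, labels).astype(labels.dtype)
    return new_labels, move


def finalize_probabilistic(
    labels: np.ndarray,
    priors_at_voxels: np.ndarray,
    distance_weights: np.ndarray,
    stack: ChannelStack,
) -> list[VolumetricImage]:
    """final_prob_c(v) = [label(v) = c] * prior_c(v) * w(v).

    Exactly one channel is nonzero per masked voxel; all channels are zero
    outside the tissue mask.
    """
    n = labels.shape[0]
    idx = np.arange(n)
    out = []
    for c in range(1, 7):
        per_voxel = np.where(
            labels == c, priors_at_voxels[idx, c - 1] * distance_weights, 0.0
        )
        out.append(stack.volume_from(per_voxel))
    return out


def refine_subject(
    model: ClusterModel,
    stack: ChannelStack,
    priors_subject: list[VolumetricImage],
    p_high: float = P_HIGH,
    p_margin: float = P_MARGIN,
) -> SegmentationResult:
    """One refinement pass: consistency check, reassignment, probabilities.

    Distance weights are recomputed per cluster after reassignment, with a
    moved voxel's distance taken to its new centroid, keeping the weight
    semantics tied to the final cluster membership.
    """
    idx = tuple(stack.voxel_index.T)
    priors_at_voxels = np.column_stack([p.data[idx] for p in priors_subject])
    new_labels, moved = reassign_inconsistent(model.labels, priors_at_voxels, p_high, p_margin)

    distances = model.distances.copy()
    if moved.any():
        z = stack.zscores[moved]
        distances[moved] = np.linalg.norm(
            z - model.centroids[new_labels[moved] - 1], axis=1
        )
    remodel = ClusterModel(
        k=model.k,
        centroids=model.centroids,
        labels=new_labels,
        distances=distances,
        inertia=model.inertia,
        silhouettes=model.silhouettes,
    )
    weights = standardize_distances(remodel)
    probs = finalize_probabilistic(new_labels, priors_at_voxels, weights, stack)
    lab_img = stack.volume_from(new_labels.astype(float))
    return SegmentationResult(
        final_probs=probs,
        final_labels=lab_img.with_data(lab_img.data.astype(np.int16)),
        reassigned_mask=stack.volume_from(moved.astype(float)),
        distance_weights=stack.volume_from(weights),
    )
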