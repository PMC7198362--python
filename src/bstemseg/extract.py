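"""Brainstem channel-stack extraction and standardization.

The three calibrated whole-brain channels (UNI_cal, T1map_cal, RATIO) are
restricted to the brainstem/thalamus label, reduced to a per-voxel feature
table, and z-scored per channel.  The z-scored triplets are the feature
space in which clustering, silhouettes and centroid distances live.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import VolumetricImage, require_same_grid

__all__ = ["ChannelStack", "extract_brainstem", "make_tissue_mask", "build_stack", "standardize"]

CHANNELS = ("uni", "t1map", "ratio")
# bs_UNI threshold for the clustering tissue mask: half the dark anchor
# (Ref2/2), excluding residual near-zero CSF-adjacent voxels while keeping
# the boundary shell.
DEFAULT_TISSUE_THRESHOLD = 10.0
_MIN_CLUSTER_SUPPORT = 50


@dataclass
class ChannelStack:
    """Per-voxel feature table over the brainstem tissue mask.

    ``voxel_index`` holds the (x, y, z) coordinate of every included voxel
    on ``grid``; ``values`` is the (n, c) raw channel matrix and ``zscores``
    its per-channel standardization (sample sd, n - 1 in the denominator,
    the MATLAB ``zscore`` convention).
    """

    voxel_index: np.ndarray  # (n, 3) int
    values: np.ndarray  # (n, n_channels) float
    zscores: np.ndarray | None
    grid: VolumetricImage  # reference geometry (tissue mask as data)
    channel_names: tuple[str, ...] = CHANNELS

    def __len__(self) -> int:
        return self.voxel_index.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def volume_from(self, per_voxel: np.ndarray, fill: float = 0.0) -> VolumetricImage:
        """Scatter a per-voxel vector back into a volume on the grid."""
        out = np.full(self.grid.shape, fill, dtype=float)
        idx = tuple(self.voxel_index.T)
        out[idx] = per_voxel
        return self.grid.with_data(out)

    def select_channels(self, names) -> "ChannelStack":
        """Sub-stack restricted to the named channels (re-standardized)."""
        cols = [self.channel_names.index(n) for n in names]
        sub = ChannelStack(
            voxel_index=self.voxel_index,
            values=self.values[:, cols],
            zscores=None,
            grid=self.grid,
            channel_names=tuple(names),
        )
        return standardize(sub)


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def extract_brainstem(
    uni_cal: VolumetricImage,
    t1map_cal: VolumetricImage,
    ratio: VolumetricImage,
    bs_label: VolumetricImage,
) -> dict:
    """Zero the channels outside the brainstem label and crop to its
    bounding box (affine translated accordingly).  Returns the cropped
    channels plus the cropped label under key ``"label"``."""
    require_same_grid(uni_cal, t1map_cal, ratio, bs_label)
    mask = bs_label.data > 0
    if not mask.any():
        raise ValueError("brainstem label is empty")
    box = _bounding_box(mask)
    offset = np.array([s.start for s in box], dtype=float)
    affine = bs_label.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ offset
    cropped_mask = mask[box]
    out = {}
    for name, img in (("uni", uni_cal), ("t1map", t1map_cal), ("ratio", ratio)):
        data = np.where(mask, img.data, 0.0)[box]
        out[name] = VolumetricImage(data, affine)
    out["label"] = VolumetricImage(cropped_mask.astype(np.uint8), affine)
    return out


def make_tissue_mask(
    bs_uni: VolumetricImage,
    bs_label: VolumetricImage | None = None,
    threshold: float = DEFAULT_TISSUE_THRESHOLD,
    k: int = 6,
) -> VolumetricImage:
    """Binary mask of voxels participating in clustering:
    bs_UNI > threshold inside the brainstem label."""
    mask = np.asarray(bs_uni.data) > threshold
    if bs_label is not None:
        mask &= np.asarray(bs_label.data) > 0
    n = int(mask.sum())
    if n < k * _MIN_CLUSTER_SUPPORT:
        raise ValueError(
            f"tissue mask has only {n} voxels; need at least "
            f"{k * _MIN_CLUSTER_SUPPORT} to support {k} clusters"
        )
    return bs_uni.with_data(mask.astype(np.uint8))


def build_stack(
    channels: dict, tissue_mask: VolumetricImage, standardized: bool = True
) -> ChannelStack:
    """Assemble the per-voxel channel table over the tissue mask."""
    mask = tissue_mask.data > 0
    imgs = [channels[c] for c in CHANNELS]
    require_same_grid(*imgs, tissue_mask)
    idx = np.argwhere(mask)
    values = np.column_stack([img.data[mask].astype(float) for img in imgs])
    stack = ChannelStack(idx, values, None, tissue_mask.with_data(mask.astype(np.uint8)))
    return standardize(stack) if standardized else stack


def standardize(stack: ChannelStack) -> ChannelStack:
    """Z-score each channel over the included voxels (sample sd, n - 1)."""
    if len(stack) < 2:
        raise ValueError("need at least 2 voxels to standardize")
    mean = stack.values.mean(axis=0)
    sd = stack.values.std(axis=0, ddof=1)
    for c, s in zip(stack.channel_names, sd):
        if s == 0:
            raise ValueError(f"channel {c!r} has zero variance; cannot z-score")
    return ChannelStack(
        voxel_index=stack.voxel_index,
        values=stack.values,
        zscores=(stack.values - mean) / sd,
        grid=stack.grid,
        channel_names=stack.channel_names,
    )
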