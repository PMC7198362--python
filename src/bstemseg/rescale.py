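"""Anchored linear intensity rescaling and RATIO-image construction.

MP2RAGE intensities are in arbitrary scanner units that vary between
subjects and field strengths.  This module pins each subject's histogram to
two fixed anchors: the white-matter histogram mode and the CSF histogram
mode (estimated over high-confidence tissue voxels, vessels excluded by a
percentile cut) are mapped linearly onto reference values Ref1 = 100
(bright anchor) and Ref2 = 20 (dark anchor).  On the T1-weighted UNI image
white matter is bright (wm -> Ref1, csf -> Ref2); on the T1 relaxation map
the ordering reverses (wm -> Ref2, csf -> Ref1).  Compressing both images
onto the same narrow range roughly doubles the gray/white contrast and
makes the voxelwise quotient UNI_cal / T1map_cal (the RATIO image) a third,
even higher-contrast channel.

The linear map can push a few voxels negative and the quotient can blow up
where the denominator is small; both are repaired from their 6-connected
neighborhoods rather than clipped, so local structure is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VolumetricImage, require_same_grid

__all__ = [
    "RescaleParams",
    "ScaleFactors",
    "estimate_tissue_mode",
    "compute_scale_factors",
    "apply_rescale",
    "repair_negative_voxels",
    "compute_ratio",
    "compute_contrast",
    "rescale_subject",
]

_MIN_MODE_VOXELS = 100
_N_BINS = 256


@dataclass(frozen=True)
class RescaleParams:
    """Reference anchors and exclusion thresholds for the linear rescaling."""

    ref1: float = 100.0  # bright anchor
    ref2: float = 20.0  # dark anchor
    tissue_prob_threshold: float = 0.9
    vessel_low_pct: float = 1.0  # T1 map: exclude below this percentile
    vessel_high_pct: float = 95.0  # UNI: exclude above this percentile
    ratio_cap_pct: float = 99.0

    def __post_init__(self) -> None:
        if not (self.ref1 > self.ref2 > 0):
            raise ValueError("require ref1 > ref2 > 0")
        if not (0 < self.tissue_prob_threshold < 1):
            raise ValueError("tissue_prob_threshold must be in (0, 1)")
        if not (0 <= self.vessel_low_pct < self.vessel_high_pct <= 100):
            raise ValueError("require 0 <= vessel_low_pct < vessel_high_pct <= 100")


@dataclass(frozen=True)
class ScaleFactors:
    """Linear map out = in * fact - shift anchored at the two tissue modes."""

    fact: float
    shift: float
    wm_mode: float
    csf_mode: float
    modality: str  # "uni" | "t1map"


def estimate_tissue_mode(
    image: VolumetricImage,
    tissue_prob: VolumetricImage,
    params: RescaleParams,
    tissue: str,
    modality: str,
) -> float:
    """Histogram mode of high-confidence ``tissue`` voxels, vessels excluded.

    Voxels with tissue probability above ``tissue_prob_threshold`` enter the
    histogram; intensities below the ``vessel_low_pct`` percentile (T1 map)
    or above ``vessel_high_pct`` (UNI) are excluded first, since vessels
    appear as intensity outliers in those directions.  The mode is the
    center of the fullest of 256 equal-width bins (ties toward the lower
    bin).
    """
    require_same_grid(image, tissue_prob)
    vals = image.data[tissue_prob.data > params.tissue_prob_threshold].astype(float)
    if vals.size < _MIN_MODE_VOXELS:
        raise ValueError(
            f"only {vals.size} voxels exceed probability "
            f"{params.tissue_prob_threshold} for tissue {tissue!r}; "
            "upstream tissue map looks unusable"
        )
    if modality == "t1map":
        vals = vals[vals >= np.percentile(vals, params.vessel_low_pct)]
    elif modality == "uni":
        vals = vals[vals <= np.percentile(vals, params.vessel_high_pct)]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(vals, bins=_N_BINS, range=(lo, hi))
    best = int(np.argmax(counts))  # argmax returns the first (lowest) max bin
    return float(0.5 * (edges[best] + edges[best + 1]))


def compute_scale_factors(
    wm_mode: float, csf_mode: float, params: RescaleParams, modality: str
) -> ScaleFactors:
    """Scale factor and shift mapping the two tissue modes onto the anchors.

    uni:   wm_mode -> ref1, csf_mode -> ref2   (wm bright)
    t1map: wm_mode -> ref2, csf_mode -> ref1   (wm dark)

    fact = |ref1 - ref2| / |wm_mode - csf_mode|; the shift follows from
    requiring both anchor identities to hold exactly.
    """
    if wm_mode == csf_mode:
        raise ValueError("wm and csf modes coincide; cannot anchor the rescaling")
    if modality == "uni":
        if not wm_mode > csf_mode:
            raise ValueError(
                "UNI anchor ordering violated (expected wm_mode > csf_mode); "
                "tissue maps may be swapped"
            )
        fact = (params.ref1 - params.ref2) / (wm_mode - csf_mode)
        shift = (csf_mode * params.ref1 - wm_mode * params.ref2) / (wm_mode - csf_mode)
    elif modality == "t1map":
        if not csf_mode > wm_mode:
            raise ValueError(
                "T1map anchor ordering violated (expected csf_mode > wm_mode); "
                "tissue maps may be swapped"
            )
        fact = (params.ref1 - params.ref2) / (csf_mode - wm_mode)
        shift = (wm_mode * params.ref1 - csf_mode * params.ref2) / (csf_mode - wm_mode)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return ScaleFactors(float(fact), float(shift), float(wm_mode), float(csf_mode), modality)


def apply_rescale(
    image: VolumetricImage, sf: ScaleFactors, brain_mask: VolumetricImage
) -> VolumetricImage:
    """out = image * fact - shift inside the mask, 0 outside (no repair yet)."""
    require_same_grid(image, brain_mask)
    mask = brain_mask.data > 0
    out = np.zeros(image.shape, dtype=float)
    out[mask] = image.data[mask] * sf.fact - sf.shift
    return image.with_data(out)


_SIX_CONN = ndimage.generate_binary_structure(3, 1).astype(float)
_SIX_CONN[1, 1, 1] = 0.0


def _neighbor_sum_count(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of qualifying 6-connected neighbors at every voxel."""
    v = np.where(valid, values.astype(float), 0.0)
    total = ndimage.correlate(v, _SIX_CONN, mode="constant")
    count = ndimage.correlate(valid.astype(float), _SIX_CONN, mode="constant")
    return total, count


def repair_negative_voxels(
    image: VolumetricImage, brain_mask: VolumetricImage
) -> VolumetricImage:
    """Replace masked negative voxels by the mean of their non-negative
    6-connected masked neighbors (single pass over the original values);
    negatives with no qualifying neighbor become 0."""
    require_same_grid(image, brain_mask)
    mask = brain_mask.data > 0
    data = image.data.astype(float)
    negative = mask & (data < 0)
    if not negative.any():
        return image.with_data(data.copy())
    valid = mask & (data >= 0)
    total, count = _neighbor_sum_count(data, valid)
    out = data.copy()
    repairable = negative & (count > 0)
    out[repairable] = total[repairable] / count[repairable]
    out[negative & (count == 0)] = 0.0
    return image.with_data(out)


def compute_ratio(
    uni_cal: VolumetricImage,
    t1map_cal: VolumetricImage,
    params: RescaleParams,
    brain_mask: VolumetricImage,
) -> VolumetricImage:
    """RATIO = UNI_cal / T1map_cal inside the mask, outliers repaired.

    The denominator is floored at a tiny fraction of its masked median.
    Masked voxels above the ``ratio_cap_pct`` percentile are replaced by the
    mean of 6-connected masked neighbors at or below that percentile; a
    super-percentile voxel with no qualifying neighbor is set to the
    percentile value itself.
    """
    require_same_grid(uni_cal, t1map_cal, brain_mask)
    mask = brain_mask.data > 0
    denom = t1map_cal.data.astype(float)
    med = float(np.median(denom[mask])) if mask.any() else 1.0
    eps = max(abs(med) * 1e-6, 1e-12)
    ratio = np.zeros(uni_cal.shape, dtype=float)
    ratio[mask] = uni_cal.data[mask] / np.maximum(denom[mask], eps)

    cap = float(np.percentile(ratio[mask], params.ratio_cap_pct))
    above = mask & (ratio > cap)
    if above.any():
        valid = mask & (ratio <= cap)
        total, count = _neighbor_sum_count(ratio, valid)
        repl = above & (count > 0)
        ratio[repl] = total[repl] / count[repl]
        ratio[above & (count == 0)] = cap
    return uni_cal.with_data(ratio)


def compute_contrast(
    image: VolumetricImage, roi_bright: np.ndarray, roi_dark: np.ndarray
) -> float:
    """mean(image | bright ROI) / mean(image | dark ROI)."""
    roi_bright = np.asarray(roi_bright) > 0
    roi_dark = np.asarray(roi_dark) > 0
    if not roi_bright.any() or not roi_dark.any():
        raise ValueError("both ROIs must be nonempty")
    dark_mean = float(image.data[roi_dark].mean())
    if dark_mean <= 0:
        raise ValueError(f"dark-ROI mean is {dark_mean}; contrast undefined")
    return float(image.data[roi_bright].mean()) / dark_mean


def rescale_subject(
    uni: VolumetricImage,
    t1map: VolumetricImage,
    tissue_probs: dict,
    brain_mask: VolumetricImage,
    params: RescaleParams | None = None,
) -> dict:
    """Full per-subject rescaling: modes -> factors -> rescale -> repair -> RATIO.

    Returns a dict with ``uni_cal``, ``t1map_cal``, ``ratio`` images and the
    two :class:`ScaleFactors` (for logging).
    """
    params = params or RescaleParams()
    out: dict = {}
    cal = {}
    for modality, img in (("uni", uni), ("t1map", t1map)):
        wm = estimate_tissue_mode(img, tissue_probs["wm"], params, "wm", modality)
        csf = estimate_tissue_mode(img, tissue_probs["csf"], params, "csf", modality)
        sf = compute_scale_factors(wm, csf, params, modality)
        cal[modality] = repair_negative_voxels(apply_rescale(img, sf, brain_mask), brain_mask)
        out[f"factors_{modality}"] = sf
    out["uni_cal"] = cal["uni"]
    out["t1map_cal"] = cal["t1map"]
    out["ratio"] = compute_ratio(cal["uni"], cal["t1map"], params, brain_mask)
    return out
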