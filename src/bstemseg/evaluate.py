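"""Segmentation quality indices, ROI extraction and group statistics.

Two complementary quality surfaces summarize a clustering run:

* the **low-silhouette index** — for every cluster except the CSF/tissue
  partial-volume cluster, the percentage of voxels with silhouette > 0.6,
  averaged over the five clusters.  High values mean cluster assignments are
  supported by the feature geometry.
* the **miss-classification index** — the percentage of first-pass voxels
  of each cluster that fall outside that cluster's subject-space prior
  thresholded at 0.3, averaged over clusters.  High values mean voxels were
  assigned to clusters they do not spatially belong to (typically noise).

Alongside, a generic ROI mean-intensity extractor and the group-comparison
helpers: Shapiro-Wilk gated t vs rank tests and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterModel
from .image import VolumetricImage

__all__ = [
    "QualityReport",
    "low_silhouette_index",
    "missclassification_index",
    "roi_mean_intensities",
    "group_compare",
    "fdr_correct",
    "dice_scores",
]

SILHOUETTE_THRESHOLD = 0.6
PRIOR_THRESHOLD = 0.3
PARTIAL_VOLUME_CLUSTER = 2


@dataclass
class QualityReport:
    """Per-run quality summary (one row of the performance table)."""

    input_combo: str
    low_silhouette_index: float  # percent
    missclassification_index: float  # percent
    missclass_std_distance: float  # mean standardized weight of missclassified voxels
    per_cluster: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_combo": self.input_combo,
            "low_silhouette_index": self.low_silhouette_index,
            "missclassification_index": self.missclassification_index,
            "missclass_std_distance": self.missclass_std_distance,
            "per_cluster": self.per_cluster,
        }


def low_silhouette_index(
    model: ClusterModel,
    excluded_cluster: int = PARTIAL_VOLUME_CLUSTER,
    threshold: float = SILHOUETTE_THRESHOLD,
) -> float:
    """Mean over clusters (excluding the partial-volume one) of the
    percentage of voxels with silhouette strictly above ``threshold``."""
    if model.silhouettes is None:
        raise ValueError("silhouettes have not been computed for this model")
    pcts = []
    for c in range(1, model.k + 1):
        if c == excluded_cluster:
            continue
        sel = model.labels == c
        if not sel.any():
            continue  # empty cluster: excluded from the mean
        pcts.append(100.0 * float((model.silhouettes[sel] > threshold).mean()))
    return float(np.mean(pcts))


def missclassification_index(
    binary_maps: list[VolumetricImage],
    priors_subject: list[VolumetricImage],
    distance_weights: VolumetricImage | None = None,
    prior_threshold: float = PRIOR_THRESHOLD,
) -> tuple[float, dict, float]:
    """Fraction of first-pass voxels outside their thresholded prior.

    Per cluster c: miss_c = 100 * |{map_c = 1 and prior_c < threshold}| /
    |{map_c = 1}|; the index is the mean over nonempty clusters.  Also
    returns the per-cluster percentages and, when distance weights are
    given, the mean standardized distance weight of miss-classified voxels.
    """
    per_cluster: dict = {}
    miss_weights = []
    for c, (bmap, prior) in enumerate(zip(binary_maps, priors_subject), start=1):
        sel = np.asarray(bmap.data) > 0.5
        n = int(sel.sum())
        if n == 0:
            continue
        outside = sel & (np.asarray(prior.data) < prior_threshold)
        per_cluster[c] = 100.0 * float(outside.sum()) / n
        if distance_weights is not None and outside.any():
            miss_weights.append(distance_weights.data[outside])
    index = float(np.mean(list(per_cluster.values()))) if per_cluster else 0.0
    mean_w = float(np.concatenate(miss_weights).mean()) if miss_weights else float("nan")
    return index, per_cluster, mean_w


def roi_mean_intensities(images: dict, roi_labels: VolumetricImage) -> pd.DataFrame:
    """Mean intensity of each labeled ROI in each image.

    Returns a DataFrame indexed by ROI label with one column per image;
    empty ROIs yield NaN.
    """
    lab = np.asarray(roi_labels.data).astype(int)
    rois = sorted(int(r) for r in np.unique(lab) if r != 0)
    rows = {}
    for r in rois:
        sel = lab == r
        rows[r] = {
            name: (float(img.data[sel].mean()) if sel.any() else float("nan"))
            for name, img in images.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("roi")


def group_compare(
    values_a, values_b, paired: bool = False, alpha_normality: float = 0.05
) -> tuple[float, float, str]:
    """Normality-gated two-group comparison.

    Shapiro-Wilk at alpha 0.05 on each group (differences, when paired)
    selects a t-test when both pass, a rank test otherwise (Wilcoxon
    signed-rank when paired, Mann-Whitney U when not).  Returns
    (statistic, p, test_name).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if a.std() == 0 and b.std() == 0:
        if paired and np.array_equal(a, b):
            return 0.0, 1.0, "wilcoxon_degenerate"
        raise ValueError("zero variance in both groups")
    if paired:
        diff = a - b
        normal = stats.shapiro(diff).pvalue > alpha_normality if diff.std() > 0 else False
        if normal:
            res = stats.ttest_rel(a, b)
            return float(res.statistic), float(res.pvalue), "paired_t"
        if np.all(diff == 0):
            return 0.0, 1.0, "wilcoxon_degenerate"
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank"
    normal = (
        (a.std() > 0 and stats.shapiro(a).pvalue > alpha_normality)
        and (b.std() > 0 and stats.shapiro(b).pvalue > alpha_normality)
    )
    if normal:
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue), "t"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), "mannwhitney_u"


def dice_scores(
    predicted: np.ndarray, truth: np.ndarray, n_classes: int = 6, match: bool = True
) -> dict:
    """Per-class Dice between two label volumes.

    Cluster numbering is arbitrary relative to ground truth, so by default
    the predicted labels are first matched one-to-one to the truth labels
    by maximizing total overlap (Hungarian assignment on the class overlap
    matrix); ``match=False`` compares the numbering as-is.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    classes = list(range(1, n_classes + 1))
    if match:
        from scipy.optimize import linear_sum_assignment

        overlap = np.zeros((n_classes, n_classes))
        for i, cp in enumerate(classes):
            psel = predicted == cp
            for j, ct in enumerate(classes):
                overlap[i, j] = np.sum(psel & (truth == ct))
        row, col = linear_sum_assignment(-overlap)
        mapping = {classes[r]: classes[c] for r, c in zip(row, col)}
        relabeled = np.zeros_like(predicted)
        for cp, ct in mapping.items():
            relabeled[predicted == cp] = ct
        predicted = relabeled
    out = {}
    for c in classes:
        p = predicted == c
        t = truth == c
        denom = int(p.sum()) + int(t.sum())
        out[c] = 2.0 * float(np.sum(p & t)) / denom if denom else float("nan")
    return out


def fdr_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR over a family of comparisons.

    Returns (reject flags, adjusted p-values).
    """
    reject, p_adj, _, _ = multipletests(np.asarray(pvalues, float), alpha=q, method="fdr_bh")
    return reject, p_adj
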