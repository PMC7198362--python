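"""Deformation-based morphometry on the template-building transforms.

Each subject's deformation encodes where and how much their anatomy had to
expand or contract to match the group template.  The Jacobian determinant of
the forward map (template-grid point x -> subject-space point x + u(x)) is a
dimensionless local volume-change ratio: values above 1 mean the subject is
locally larger than the template, below 1 locally smaller — so regional
volume loss in a group shows up as Jacobians below the other group's.

Group comparison is a voxelwise two-sample pooled-variance t statistic with
family-wise error controlled by a permutation max-T null: group labels are
permuted, the maximum |t| over the analysis mask recorded, and the observed
map thresholded at the (1 - alpha) quantile of that null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import VolumetricImage
from .warpfield import DeformationField

__all__ = ["JacobianMap", "jacobian_from_deformation", "dbm_group_test"]


@dataclass
class JacobianMap:
    """Per-voxel volume-change ratio of one subject's forward deformation."""

    values: VolumetricImage
    subject_id: object = None


def jacobian_from_deformation(field: DeformationField, subject_id=None) -> JacobianMap:
    """Determinant of the spatial gradient of x -> x + u(x).

    Central finite differences in the interior, one-sided at the boundary
    (numpy.gradient), with voxel spacing respected.  A diffeomorphic field
    must yield strictly positive determinants everywhere; any non-positive
    value raises.
    """
    spacing = field.spacing
    u = field.displacement  # mm
    coords = [np.arange(n) * spacing[i] for i, n in enumerate(u.shape[1:])]
    jac = np.zeros((*u.shape[1:], 3, 3))
    for i in range(3):
        grads = np.gradient(u[i], *coords)
        for j in range(3):
            jac[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    det = np.linalg.det(jac)
    n_bad = int((det <= 0).sum())
    if n_bad:
        raise ValueError(
            f"deformation is folded: {n_bad} voxels with non-positive Jacobian determinant"
        )
    return JacobianMap(VolumetricImage(det, field.affine), subject_id)


def _tstat(data: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per voxel; data is (n_subjects, n_voxels)."""
    a = data[in_a]
    b = data[~in_a]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(np.isfinite(t), t, 0.0)


def dbm_group_test(
    jacobians_a: list[JacobianMap],
    jacobians_b: list[JacobianMap],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> dict:
    """Voxelwise group comparison of Jacobian maps with max-T FWE control.

    Returns a dict with the t map, the FWE threshold, the significant-voxel
    mask (|t| above threshold) and bookkeeping (n_permutations, seed).
    ``mask`` restricts the analysis (default: all voxels).
    """
    if len(jacobians_a) < 3 or len(jacobians_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    if n_permutations < 20:
        raise ValueError("fewer than 20 permutations cannot control FWE")
    import warnings

    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse FWE threshold")

    ref = jacobians_a[0].values
    shape = ref.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask) > 0
    all_maps = jacobians_a + jacobians_b
    data = np.stack([np.asarray(j.values.data)[mask] for j in all_maps])
    n_a = len(jacobians_a)
    n = data.shape[0]
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True

    t_obs = _tstat(data, in_a)
    # Exact test when the assignment space is small enough: enumerate every
    # group labeling (invariant to subject order within groups); otherwise
    # draw a seeded random subset.
    from math import comb

    if comb(n, n_a) <= n_permutations:
        from itertools import combinations

        assignments = []
        for picks in combinations(range(n), n_a):
            flags = np.zeros(n, dtype=bool)
            flags[list(picks)] = True
            assignments.append(flags)
    else:
        rng = np.random.default_rng(seed)
        assignments = [in_a[rng.permutation(n)] for _ in range(n_permutations)]
    max_t = np.array([np.abs(_tstat(data, flags)).max() for flags in assignments])
    threshold = float(np.quantile(max_t, 1.0 - alpha))

    tmap = np.zeros(shape)
    tmap[mask] = t_obs
    sig = np.zeros(shape, dtype=bool)
    sig[mask] = np.abs(t_obs) > threshold
    return {
        "tmap": VolumetricImage(tmap, ref.affine),
        "fwe_threshold": threshold,
        "significant_mask": VolumetricImage(sig.astype(np.uint8), ref.affine),
        "n_significant": int(sig.sum()),
        "n_permutations": n_permutations,
        "alpha": alpha,
        "seed": seed,
    }
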