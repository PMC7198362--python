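"""Probabilistic cluster priors by iterative diffeomorphic template building.

The six binary first-pass cluster maps of every subject are registered
jointly (multi-channel sum-of-squared-differences) to an evolving group
average, in the spirit of DARTEL's "create template": average the maps,
register every subject to the average, re-average the warped maps, repeat.
Transforms are diffeomorphisms parameterized by stationary velocity fields
and estimated by a log-demons scheme — a bounded demons force accumulated
into the velocity with Gaussian fluid/diffusion regularization — so every
forward map has positive Jacobian determinant and an exact-by-construction
inverse (exp of the negated velocity).

The final averages are the priors: prior_c(v) near 1 means nearly every
subject's cluster c covered template voxel v.  The inverse transforms
project the priors back into each subject's space, where the refinement
stage consumes them.  An implicit background channel (1 - sum of maps)
joins the registration to stabilize the outer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import VolumetricImage, require_same_grid
from .warpfield import DeformationField, exp_velocity, warp_volume

__all__ = ["RegistrationParams", "PriorSet", "build_group_template", "warp_priors_to_subject"]


@dataclass(frozen=True)
class RegistrationParams:
    """Log-demons and template-building knobs (voxel units).

    ``update_sigma`` smooths each demons update (fluid-like), ``velocity_sigma``
    smooths the accumulated velocity (diffusion-like); ``step`` scales the
    bounded demons force, and ``n_demons_iterations`` are run per subject per
    outer template iteration.
    """

    n_outer_iterations: int = 3
    n_demons_iterations: int = 10
    update_sigma: float = 1.0
    velocity_sigma: float = 1.5
    step: float = 2.0
    add_background_channel: bool = True


@dataclass
class PriorSet:
    """Six probability volumes in template space + per-subject transforms."""

    priors: list  # six VolumetricImage, values in [0, 1]
    per_subject_transforms: dict  # subject_id -> DeformationField
    n_subjects: int
    cost_history: list = field(default_factory=list)  # total SSD per outer iteration
    overlap_history: list = field(default_factory=list)  # mean generalized Dice per outer iteration

    @property
    def subject_ids(self) -> list:
        return list(self.per_subject_transforms)


def _demons_step(
    fixed: np.ndarray, warped: np.ndarray
) -> tuple[np.ndarray, float]:
    """Multi-channel demons force (3, X, Y, Z) and current SSD cost.

    Least-squares combination of the per-channel Thirion forces:
    u = sum_c diff_c * grad(W_c) / (sum_c |grad(W_c)|^2 + diff_c^2),
    which bounds the voxel step at ~0.5 like the classical normalization.
    """
    num = np.zeros((3, *fixed.shape[1:]))
    den = np.zeros(fixed.shape[1:])
    cost = 0.0
    for c in range(fixed.shape[0]):
        diff = fixed[c] - warped[c]
        cost += float(np.sum(diff**2))
        grads = np.gradient(warped[c])
        for axis in range(3):
            num[axis] += diff * grads[axis]
        den += sum(g**2 for g in grads) + diff**2
    force = num / np.maximum(den, 1e-9)
    return force, cost


def _register_channels(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationParams,
    velocity: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Advance the log-demons registration of ``moving`` onto ``fixed``.

    Returns the updated velocity field and the final SSD cost.  On a
    non-finite cost or a folded exponential the step size is halved once;
    a second failure raises.
    """
    v = np.zeros((3, *fixed.shape[1:])) if velocity is None else velocity.copy()
    step = params.step
    retried = False
    it = 0
    cost = np.inf
    while it < params.n_demons_iterations:
        u = exp_velocity(v)
        warped = np.stack([warp_volume(m, u) for m in moving])
        force, cost = _demons_step(fixed, warped)
        if not np.isfinite(cost):
            if retried:
                raise RuntimeError("registration diverged (non-finite cost)")
            step *= 0.5
            retried = True
            v = np.zeros_like(v)
            it = 0
            continue
        for axis in range(3):
            force[axis] = ndimage.gaussian_filter(force[axis], params.update_sigma)
        v = v + step * force
        for axis in range(3):
            v[axis] = ndimage.gaussian_filter(v[axis], params.velocity_sigma)
        it += 1
    u = exp_velocity(v)
    if _min_jacobian(u) <= 0:
        if retried:
            raise RuntimeError("registration produced a folded transform (det J <= 0)")
        half = RegistrationParams(
            n_outer_iterations=params.n_outer_iterations,
            n_demons_iterations=params.n_demons_iterations,
            update_sigma=params.update_sigma,
            velocity_sigma=params.velocity_sigma,
            step=step * 0.5,
            add_background_channel=params.add_background_channel,
        )
        return _register_channels(fixed, moving, half, None)
    return v, cost


def _min_jacobian(disp_vox: np.ndarray) -> float:
    grads = [np.gradient(disp_vox[i]) for i in range(3)]
    jac = np.zeros((*disp_vox.shape[1:], 3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
    return float(np.linalg.det(jac).min())


def _mean_overlap(warped_all: np.ndarray, template: np.ndarray) -> float:
    """Mean per-cluster Dice between each subject's warped argmax labels and
    the template argmax labels (first six channels only); tracks how tightly
    the cohort has converged onto the evolving template."""
    tlab = np.argmax(template[:6], axis=0) + 1
    tlab[template[:6].max(axis=0) < 0.5] = 0
    dices = []
    for si in range(warped_all.shape[0]):
        slab = np.argmax(warped_all[si, :6], axis=0) + 1
        slab[warped_all[si, :6].max(axis=0) < 0.5] = 0
        for c in range(1, 7):
            a, b = slab == c, tlab == c
            denom = int(a.sum()) + int(b.sum())
            if denom:
                dices.append(2.0 * float(np.sum(a & b)) / denom)
    return float(np.mean(dices)) if dices else 0.0


def _stack_subject(maps: list, add_background: bool) -> np.ndarray:
    arr = np.stack([np.asarray(m.data, dtype=float) for m in maps])
    if add_background:
        arr = np.concatenate([arr, (1.0 - arr.sum(axis=0))[None]], axis=0)
    return arr


def build_group_template(
    binary_maps_per_subject: dict | list,
    n_iterations: int = 3,
    reg_params: RegistrationParams | None = None,
) -> PriorSet:
    """Iterative multi-channel diffeomorphic template construction.

    ``binary_maps_per_subject`` maps subject id -> list of six binary
    cluster volumes on a common grid (a plain list uses positional ids).
    Returns the final group averages (priors) and each subject's
    forward/inverse transform.
    """
    if isinstance(binary_maps_per_subject, list):
        binary_maps_per_subject = {i: m for i, m in enumerate(binary_maps_per_subject)}
    ids = list(binary_maps_per_subject)
    if len(ids) < 2:
        raise ValueError("template building needs at least 2 subjects")
    params = reg_params or RegistrationParams(n_outer_iterations=n_iterations)
    ref_img: VolumetricImage = binary_maps_per_subject[ids[0]][0]
    for sid in ids:
        require_same_grid(ref_img, *binary_maps_per_subject[sid])

    data = {
        sid: _stack_subject(binary_maps_per_subject[sid], params.add_background_channel)
        for sid in ids
    }
    n_channels = data[ids[0]].shape[0]
    velocities = {sid: None for sid in ids}
    template = np.mean([data[sid] for sid in ids], axis=0)
    cost_history = []
    overlap_history = []
    for _ in range(n_iterations):
        total_cost = 0.0
        warped_all = np.zeros((len(ids), n_channels, *ref_img.shape))
        for si, sid in enumerate(ids):
            velocities[sid], cost = _register_channels(
                template, data[sid], params, velocities[sid]
            )
            total_cost += cost
            u = exp_velocity(velocities[sid])
            warped_all[si] = np.stack([warp_volume(c, u) for c in data[sid]])
        template = warped_all.mean(axis=0)
        cost_history.append(total_cost)
        overlap_history.append(_mean_overlap(warped_all, template))

    transforms = {}
    for sid in ids:
        v = velocities[sid] if velocities[sid] is not None else np.zeros((3, *ref_img.shape))
        transforms[sid] = DeformationField.from_velocity_vox(v, ref_img.affine)
    priors = [
        VolumetricImage(np.clip(template[c], 0.0, 1.0), ref_img.affine)
        for c in range(6)
    ]
    return PriorSet(priors, transforms, len(ids), cost_history, overlap_history)


def warp_priors_to_subject(prior_set: PriorSet, subject_id) -> list[VolumetricImage]:
    """Resample the six priors into one subject's space (trilinear, clipped).

    Applies the inverse of the subject's template-building transform.
    """
    if subject_id not in prior_set.per_subject_transforms:
        raise KeyError(f"unknown subject {subject_id!r}")
    tf = prior_set.per_subject_transforms[subject_id]
    u_inv = tf.inverse_displacement_vox()
    out = []
    for prior in prior_set.priors:
        data = warp_volume(prior.data, u_inv, order=1)
        out.append(prior.with_data(np.clip(data, 0.0, 1.0)))
    return out
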