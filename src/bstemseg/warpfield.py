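"""Smooth invertible deformations via stationary velocity fields.

Deformations throughout the pipeline are diffeomorphisms parameterized by a
stationary velocity field v: the forward map is phi = exp(v) computed by
scaling and squaring, and the inverse is exp(-v).  This guarantees
invertibility (positive Jacobian determinant) for any smooth, moderately
sized velocity field, which is the contract the prior-building and
morphometry stages rely on.

Displacements handled here are in voxel units; :class:`DeformationField`
stores them in millimetres together with the grid affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DeformationField",
    "exp_velocity",
    "compose_displacements",
    "warp_volume",
    "random_smooth_velocity",
]


def _identity_grid(shape: tuple[int, ...]) -> np.ndarray:
    """Voxel-coordinate grid, shape (3, X, Y, Z)."""
    return np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    )


def warp_volume(
    data: np.ndarray,
    displacement: np.ndarray,
    order: int = 1,
    mode: str = "nearest",
) -> np.ndarray:
    """Resample ``data`` at x + u(x); u in voxel units, shape (3, X, Y, Z)."""
    coords = _identity_grid(data.shape) + displacement
    return ndimage.map_coordinates(
        np.asarray(data, dtype=float), coords, order=order, mode=mode
    )


def compose_displacements(u_outer: np.ndarray, u_inner: np.ndarray) -> np.ndarray:
    """Displacement of x -> (id + u_outer) o (id + u_inner), voxel units."""
    out = np.empty_like(u_inner)
    coords = _identity_grid(u_inner.shape[1:]) + u_inner
    for axis in range(3):
        out[axis] = u_inner[axis] + ndimage.map_coordinates(
            u_outer[axis], coords, order=1, mode="nearest"
        )
    return out


def exp_velocity(velocity: np.ndarray, n_steps: int | None = None) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring.

    ``velocity`` has shape (3, X, Y, Z) in voxel units.  The number of
    squaring steps is chosen so the scaled field moves every voxel by less
    than half a voxel, which keeps the recursive composition accurate.
    """
    v = np.asarray(velocity, dtype=float)
    max_disp = float(np.max(np.abs(v))) if v.size else 0.0
    if n_steps is None:
        n_steps = max(2, int(np.ceil(np.log2(max(max_disp, 1e-12) / 0.5))) + 1)
        n_steps = min(n_steps, 12)
    u = v / (2.0**n_steps)
    for _ in range(n_steps):
        u = compose_displacements(u, u)
    return u


def random_smooth_velocity(
    shape: tuple[int, int, int],
    rms: float,
    rng: np.random.Generator,
    sigma: float = 6.0,
) -> np.ndarray:
    """Gaussian random velocity field smoothed to correlation length ``sigma``
    (voxels) and normalized to the requested root-mean-square magnitude."""
    v = rng.standard_normal((3, *shape))
    for axis in range(3):
        v[axis] = ndimage.gaussian_filter(v[axis], sigma)
    current = float(np.sqrt(np.mean(np.sum(v**2, axis=0))))
    if current > 0:
        v *= rms / current
    return v


@dataclass
class DeformationField:
    """Forward/inverse displacement pair for one subject.

    ``displacement`` maps template-grid points to subject-space points
    (pullback convention: warping a subject volume into template space
    samples it at x + u(x)).  ``inverse_displacement`` is the exponential of
    the negated velocity and maps subject-grid points back, which is what
    projects template-space priors into subject space.  Both are stored in
    millimetres on the grid described by ``affine``.
    """

    displacement: np.ndarray  # (3, X, Y, Z), mm
    inverse_displacement: np.ndarray  # (3, X, Y, Z), mm
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    def displacement_vox(self) -> np.ndarray:
        return self.displacement / self.spacing[:, None, None, None]

    def inverse_displacement_vox(self) -> np.ndarray:
        return self.inverse_displacement / self.spacing[:, None, None, None]

    @classmethod
    def from_velocity_vox(
        cls, velocity: np.ndarray, affine: np.ndarray
    ) -> "DeformationField":
        spacing = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
        fwd = exp_velocity(velocity)
        inv = exp_velocity(-velocity)
        s = spacing[:, None, None, None]
        return cls(fwd * s, inv * s, np.asarray(affine, dtype=float))

    @classmethod
    def identity(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "DeformationField":
        zero = np.zeros((3, *shape))
        return cls(zero, zero.copy(), np.asarray(affine, dtype=float))

    def roundtrip_rms_vox(self) -> float:
        """RMS deviation of forward-then-inverse from identity, in voxels."""
        comp = compose_displacements(
            self.inverse_displacement_vox(), self.displacement_vox()
        )
        return float(np.sqrt(np.mean(np.sum(comp**2, axis=0))))
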