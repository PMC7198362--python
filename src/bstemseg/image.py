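"""Volumetric image container shared by every pipeline stage.

All stages exchange :class:`VolumetricImage`, a thin wrapper around a 3-D
numpy array plus a 4x4 affine.  It deliberately stores no modality metadata:
the pipeline tracks which volume is which (UNI, T1 map, RATIO, mask, prior)
by variable name and filename, exactly as NIfTI-based neuroimaging tools do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumetricImage"]


@dataclass
class VolumetricImage:
    """A 3-D scalar grid with voxel spacing and affine.

    Parameters
    ----------
    data
        3-D array of voxel values (any float or integer dtype).
    affine
        4x4 voxel-to-world matrix.  Defaults to identity (1 mm isotropic).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "VolumetricImage":
        """New image on the same grid carrying ``data``."""
        return VolumetricImage(np.asarray(data), self.affine.copy())

    def copy(self) -> "VolumetricImage":
        return VolumetricImage(self.data.copy(), self.affine.copy())

    # --- NIfTI I/O ------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumetricImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))


def require_same_grid(*images: VolumetricImage) -> None:
    ref = images[0]
    for im in images[1:]:
        if not ref.same_grid(im):
            raise ValueError(
                f"images are not on a common grid: {ref.shape} vs {im.shape}"
            )
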