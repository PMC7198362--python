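"""Shared fixtures: small phantom cohorts and truth-alignment helpers."""

from __future__ import annotations

import numpy as np
import pytest

from bstemseg import PhantomSpec, generate_cohort
from bstemseg.image import VolumetricImage

SMALL_GRID = (32, 40, 28)


def crop_like(reference: VolumetricImage, target: VolumetricImage) -> np.ndarray:
    """Slice ``reference``'s data to the (translated) grid of ``target``."""
    off = np.round(
        np.linalg.inv(reference.affine[:3, :3]) @ (target.affine[:3, 3] - reference.affine[:3, 3])
    ).astype(int)
    sl = tuple(slice(o, o + n) for o, n in zip(off, target.shape))
    return reference.data[sl]


@pytest.fixture(scope="session")
def clean_cohort():
    """Two noise-free, bias-free, unjittered subjects (identical by design)."""
    spec = PhantomSpec(
        grid_shape=SMALL_GRID, noise_sd=(0, 0), bias_amplitude=0, subject_jitter=0, seed=7
    )
    return spec, generate_cohort(spec, 2)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Four subjects at the default study conditions on a small grid."""
    spec = PhantomSpec(grid_shape=SMALL_GRID, seed=7)
    return spec, generate_cohort(spec, 4)
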