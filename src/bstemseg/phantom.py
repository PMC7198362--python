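"""Synthetic multi-subject MP2RAGE-like brainstem datasets with ground truth.

The phantom emulates the statistical structure of MP2RAGE brainstem data
without any anatomical atlas: a stylized head (nested CSF / gray / white
compartments) containing an elongated tapered "brainstem" cylinder.  The
brainstem interior holds five internal tissue types with the topology the
real clusters exhibit — paired ventral tracts (label 3), paired dorsolateral
tracts (label 5), a dorsal periaqueductal-like column (label 4), a chain of
gray-matter nuclei blobs (label 6), surrounding gray matter (label 1) — and
a one-to-two-voxel CSF/tissue partial-volume shell (label 2) on the surface.

Channel intensities follow the MP2RAGE conventions: on the T1-weighted UNI
image CSF is dark and white matter bright; on the T1 relaxation map the
ordering reverses.  Two internal tissue pairs are deliberately ambiguous on
one channel each (labels 1/4 share a UNI mean, labels 3/5 share a T1 mean),
so single-channel clustering is intrinsically harder than multi-channel
clustering — the property the downstream evaluation quantifies.

Each subject is the common template geometry pushed through a small smooth
invertible warp (a random stationary velocity field), with per-channel
multiplicative bias and additive noise.  Optional "atrophy" rescales one
internal structure's size so its volume shrinks by a given factor, the
ground truth for deformation-based morphometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import VolumetricImage
from .warpfield import DeformationField, random_smooth_velocity, warp_volume

__all__ = ["PhantomSpec", "PhantomSubject", "generate_cohort", "write_cohort"]

N_TISSUES = 6
GRAY_LABELS = (1, 4, 6)
WHITE_LABELS = (3, 5)
SHELL_LABEL = 2
# volume ~ size_parameter**exponent for each resizable structure
_ATROPHY_EXPONENT = {3: 2.0, 4: 2.0, 5: 2.0, 6: 3.0}

DEFAULT_INTENSITY_MEANS = {
    # MP2RAGE-like scanner units.  "csf"/"gm"/"wm" are the head compartments
    # surrounding the brainstem; integers are the six brainstem classes.
    # Labels 1 and 4 share a UNI mean and labels 3 and 5 are close on both
    # single channels, so one-channel clustering is intrinsically ambiguous
    # while the joint (UNI, T1, RATIO) feature space separates all six.
    "uni": {1: 2000.0, 2: 1500.0, 3: 3000.0, 4: 2000.0, 5: 2800.0, 6: 2400.0,
            "csf": 1000.0, "gm": 2100.0, "wm": 3100.0},
    "t1map": {1: 1600.0, 2: 2800.0, 3: 1050.0, 4: 2000.0, 5: 1250.0, 6: 1400.0,
              "csf": 4000.0, "gm": 1700.0, "wm": 900.0},
}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    ``noise_sd`` is the additive per-channel noise in raw scanner units
    (uni, t1map); ``bias_amplitude`` the relative RMS amplitude of the smooth
    multiplicative field; ``subject_jitter`` the RMS voxel displacement of
    the per-subject random warp; ``atrophy`` an optional (label, volume
    scale) pair applied to every subject of the cohort.
    """

    grid_shape: tuple[int, int, int] = (48, 56, 40)
    voxel_size_mm: float = 1.0
    n_tissues: int = N_TISSUES
    intensity_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MEANS.items()}
    )
    noise_sd: tuple[float, float] = (60.0, 60.0)
    bias_amplitude: float = 0.03
    subject_jitter: float = 1.2
    atrophy: tuple[int, float] | None = None
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues != N_TISSUES:
            raise ValueError(f"n_tissues is fixed at {N_TISSUES}")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 16")
        if min(self.noise_sd) < 0 or self.bias_amplitude < 0 or self.subject_jitter < 0:
            raise ValueError("noise_sd, bias_amplitude and subject_jitter must be >= 0")
        self._check_ordering()
        if self.atrophy is not None:
            label, scale = self.atrophy
            if label not in _ATROPHY_EXPONENT:
                raise ValueError(
                    f"atrophy supported for structural labels {sorted(_ATROPHY_EXPONENT)}, got {label}"
                )
            if not 0 < scale:
                raise ValueError("atrophy scale must be positive")

    def _check_ordering(self) -> None:
        uni, t1 = self.intensity_means["uni"], self.intensity_means["t1map"]
        grays_u = [uni[k] for k in GRAY_LABELS]
        whites_u = [uni[k] for k in WHITE_LABELS]
        if not (uni["csf"] < min(grays_u) and max(grays_u) < min(whites_u)):
            raise ValueError(
                "UNI intensity ordering violated: require csf_mean < gray means < white means"
            )
        grays_t = [t1[k] for k in GRAY_LABELS]
        whites_t = [t1[k] for k in WHITE_LABELS]
        if not (max(whites_t) < min(grays_t) and max(grays_t) < t1["csf"]):
            raise ValueError(
                "T1map intensity ordering violated: require white means < gray means < csf_mean"
            )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class PhantomSubject:
    """One synthetic subject: images, input tissue maps, and ground truth."""

    uni: VolumetricImage
    t1map: VolumetricImage
    tissue_probs: dict  # {"csf": VolumetricImage, "gm": ..., "wm": ...}
    brainstem_mask: VolumetricImage
    truth_labels: VolumetricImage
    truth_warp: DeformationField

    @property
    def head_mask(self) -> np.ndarray:
        total = sum(p.data for p in self.tissue_probs.values())
        return np.asarray(total) > 0.5


# --------------------------------------------------------------------------
# Template geometry
# --------------------------------------------------------------------------

def _template_regions(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (truth_labels, head_region) on the template grid.

    head_region codes: 0 air, 1 csf, 2 gm, 3 wm, 4 brainstem.
    """
    nx, ny, nz = spec.grid_shape
    X, Y, Z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    head = (
        ((X - cx) / (0.47 * nx)) ** 2
        + ((Y - cy) / (0.49 * ny)) ** 2
        + ((Z - cz) / (0.47 * nz)) ** 2
    ) <= 1.0

    # Brainstem: tapered cylinder along y.
    y0, y1 = 0.14 * ny, 0.86 * ny
    r_max = 0.215 * min(nx, nz)
    t = np.clip((Y - y0) / (y1 - y0), 0.0, 1.0)
    r_of_y = r_max * (1.0 - 0.32 * t)
    in_span = (Y >= y0) & (Y <= y1)
    rad2 = (X - cx) ** 2 + (Z - cz) ** 2
    brainstem = in_span & (rad2 <= r_of_y**2) & head

    interior = ndimage.binary_erosion(brainstem, ndimage.generate_binary_structure(3, 1))
    shell = brainstem & ~interior

    scale = {lab: 1.0 for lab in _ATROPHY_EXPONENT}
    if spec.atrophy is not None:
        lab, vol_scale = spec.atrophy
        scale[lab] = vol_scale ** (1.0 / _ATROPHY_EXPONENT[lab])

    def tube(dx_frac: float, dz_frac: float, radius: float) -> np.ndarray:
        """Tube parallel to the brainstem axis at a fractional radial offset."""
        ox = cx + dx_frac * r_of_y
        oz = cz + dz_frac * r_of_y
        return in_span & (((X - ox) ** 2 + (Z - oz) ** 2) <= radius**2)

    r_unit = r_max / 8.6  # structure sizes scale with the brainstem calibre
    lab4 = tube(0.0, +0.45, 2.2 * r_unit * scale[4])
    lab3 = tube(-0.45, -0.35, 2.8 * r_unit * scale[3]) | tube(
        +0.45, -0.35, 2.8 * r_unit * scale[3]
    )
    lab5 = tube(-0.55, +0.28, 2.2 * r_unit * scale[5]) | tube(
        +0.55, +0.28, 2.2 * r_unit * scale[5]
    )
    lab6 = np.zeros_like(brainstem)
    rb = 3.2 * r_unit * scale[6]
    for frac in (0.18, 0.38, 0.58, 0.78):
        oy = y0 + frac * (y1 - y0)
        lab6 |= ((X - cx) ** 2 + (Y - oy) ** 2 + (Z - (cz - 0.08 * r_max)) ** 2) <= rb**2

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[interior] = 1
    for lab, region in ((6, lab6), (5, lab5), (3, lab3), (4, lab4)):
        labels[interior & region] = lab
    labels[shell] = SHELL_LABEL

    head_region = np.zeros(spec.grid_shape, dtype=np.int16)
    head_region[head] = 1  # csf by default
    core = ndimage.binary_erosion(head, iterations=3)
    # white-matter slab on one side, gray matter elsewhere in the core
    head_region[core & (X < cx - r_max - 3)] = 3
    head_region[core & (X >= cx - r_max - 3)] = 2
    head_region[brainstem] = 4
    return labels, head_region


def _intensity_volume(labels: np.ndarray, head_region: np.ndarray, means: dict) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=float)
    out[head_region == 1] = means["csf"]
    out[head_region == 2] = means["gm"]
    out[head_region == 3] = means["wm"]
    for lab in range(1, N_TISSUES + 1):
        out[labels == lab] = means[lab]
    return out


def _tissue_prob_volumes(labels: np.ndarray, head_region: np.ndarray) -> dict:
    shape = labels.shape
    probs = {k: np.zeros(shape) for k in ("csf", "gm", "wm")}
    probs["csf"][head_region == 1] = 1.0
    probs["gm"][head_region == 2] = 1.0
    probs["wm"][head_region == 3] = 1.0
    for lab in GRAY_LABELS:
        probs["gm"][labels == lab] = 1.0
    for lab in WHITE_LABELS:
        probs["wm"][labels == lab] = 1.0
    shell = labels == SHELL_LABEL
    probs["csf"][shell] = 0.5
    probs["gm"][shell] = 0.5
    return probs


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def generate_cohort(spec: PhantomSpec, n_subjects: int) -> list[PhantomSubject]:
    """Generate ``n_subjects`` deformed, biased, noisy copies of the template.

    Deterministic: identical (spec, seed) give bit-identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    labels_t, head_t = _template_regions(spec)
    uni_means = spec.intensity_means["uni"]
    t1_means = spec.intensity_means["t1map"]
    uni_t = _intensity_volume(labels_t, head_t, uni_means)
    t1_t = _intensity_volume(labels_t, head_t, t1_means)
    affine = spec.affine

    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng([int(spec.seed) % (2**31), i])
        if spec.subject_jitter > 0:
            vel = random_smooth_velocity(spec.grid_shape, spec.subject_jitter, rng)
            warp = DeformationField.from_velocity_vox(vel, affine)
            disp = warp.displacement_vox()
            labels = warp_volume(labels_t, disp, order=0).astype(np.int16)
            head = warp_volume(head_t, disp, order=0).astype(np.int16)
        else:
            rng.standard_normal((3, *spec.grid_shape))  # keep the stream aligned
            warp = DeformationField.identity(spec.grid_shape, affine)
            labels, head = labels_t.copy(), head_t.copy()

        uni = _intensity_volume(labels, head, uni_means)
        t1 = _intensity_volume(labels, head, t1_means)
        head_mask = head > 0

        for vol, sd in ((uni, spec.noise_sd[0]), (t1, spec.noise_sd[1])):
            if spec.bias_amplitude > 0:
                g = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), 8.0)
                g /= max(float(np.sqrt(np.mean(g[head_mask] ** 2))), 1e-12)
                vol *= np.where(head_mask, 1.0 + spec.bias_amplitude * g, 1.0)
            if sd > 0:
                if spec.rician:
                    n1 = rng.normal(0.0, sd, spec.grid_shape)
                    n2 = rng.normal(0.0, sd, spec.grid_shape)
                    noisy = np.hypot(vol + n1, n2)
                else:
                    noisy = vol + rng.normal(0.0, sd, spec.grid_shape)
                vol[head_mask] = noisy[head_mask]

        probs = _tissue_prob_volumes(labels, head)
        subjects.append(
            PhantomSubject(
                uni=VolumetricImage(uni, affine),
                t1map=VolumetricImage(t1, affine),
                tissue_probs={k: VolumetricImage(v, affine) for k, v in probs.items()},
                brainstem_mask=VolumetricImage((labels > 0).astype(np.uint8), affine),
                truth_labels=VolumetricImage(labels, affine),
                truth_warp=warp,
            )
        )
    return subjects


def template_truth(spec: PhantomSpec) -> VolumetricImage:
    """Undeformed template label volume (ground truth before subject warps)."""
    labels, _ = _template_regions(spec)
    return VolumetricImage(labels, spec.affine)


def write_cohort(subjects: list[PhantomSubject], spec: PhantomSpec, outdir) -> None:
    """Write each subject as NIfTI volumes plus a JSON sidecar of the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "intensity_means": {
            mod: {str(k): v for k, v in m.items()}
            for mod, m in spec.intensity_means.items()
        },
        "noise_sd": list(spec.noise_sd),
        "bias_amplitude": spec.bias_amplitude,
        "subject_jitter": spec.subject_jitter,
        "atrophy": list(spec.atrophy) if spec.atrophy else None,
        "rician": spec.rician,
        "seed": spec.seed,
        "n_subjects": len(subjects),
    }
    (outdir / "phantom_spec.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    for i, s in enumerate(subjects):
        sub = outdir / f"sub-{i:03d}"
        sub.mkdir(exist_ok=True)
        s.uni.save(sub / "uni.nii.gz")
        s.t1map.save(sub / "t1map.nii.gz")
        for k, v in s.tissue_probs.items():
            v.save(sub / f"prob_{k}.nii.gz")
        s.brainstem_mask.save(sub / "brainstem_mask.nii.gz")
        s.truth_labels.save(sub / "truth_labels.nii.gz")
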