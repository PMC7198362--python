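"""End-to-end orchestration of the brainstem segmentation pipeline.

Order of stages (per cohort): input-contract validation -> anchored
rescaling and RATIO construction -> brainstem extraction on a cohort-common
bounding box -> per-subject k-means first pass -> centroid matching to a
reference subject -> diffeomorphic template building (priors) -> prior
projection and rule-based refinement -> quality indices.

Everything here operates on in-memory cohorts (lists of objects exposing
``uni``, ``t1map``, ``tissue_probs``, ``brainstem_mask``); the CLI layer
handles NIfTI trees, configs and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import evaluate as _evaluate
from . import extract as _extract
from . import refine as _refine
from . import rescale as _rescale
from .image import VolumetricImage, require_same_grid
from .priors import PriorSet, RegistrationParams, build_group_template, warp_priors_to_subject

__all__ = [
    "PipelineParams",
    "SubjectResult",
    "PipelineResult",
    "run_pipeline",
    "run_input_combo_experiment",
    "run_dbm",
]

COMBOS = {
    "all3": ("uni", "t1map", "ratio"),
    "uni": ("uni",),
    "ratio": ("ratio",),
    "t1map": ("t1map",),
    "uni+t1map": ("uni", "t1map"),
    "ratio+t1map": ("ratio", "t1map"),
}


@dataclass(frozen=True)
class PipelineParams:
    """All pipeline knobs in one place (mirrors the config file sections)."""

    seed: int = 0
    k: int = 6
    kmeans_replicates: int = 100
    kmeans_max_iter: int = 1000
    reference_subject: int = 0
    tissue_threshold: float = _extract.DEFAULT_TISSUE_THRESHOLD
    rescale: _rescale.RescaleParams = field(default_factory=_rescale.RescaleParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    template_iterations: int = 3
    p_high: float = _refine.P_HIGH
    p_margin: float = _refine.P_MARGIN

    def subject_seed(self, index: int) -> int:
        return int(np.random.SeedSequence([int(self.seed) % (2**31), index]).generate_state(1)[0] % (2**31))


@dataclass
class SubjectResult:
    stack: _extract.ChannelStack
    model: _cluster.ClusterModel
    binary_maps: list
    priors_subject: list | None = None
    segmentation: _refine.SegmentationResult | None = None
    report: _evaluate.QualityReport | None = None
    scale_factors: dict | None = None


@dataclass
class PipelineResult:
    subjects: list  # SubjectResult per subject
    prior_set: PriorSet
    params: PipelineParams

    def cohort_report(self) -> pd.DataFrame:
        rows = [s.report.to_dict() for s in self.subjects if s.report is not None]
        return pd.DataFrame(
            [{k: v for k, v in r.items() if k != "per_cluster"} for r in rows]
        )


def validate_inputs(subjects) -> None:
    """Preprocessing contract: common grids, tissue probs summing to 1."""
    for i, s in enumerate(subjects):
        probs = s.tissue_probs
        require_same_grid(
            s.uni, s.t1map, s.brainstem_mask, probs["csf"], probs["gm"], probs["wm"]
        )
        total = probs["csf"].data + probs["gm"].data + probs["wm"].data
        head = total > 0.5
        if head.any() and not np.allclose(total[head], 1.0, atol=1e-3):
            raise ValueError(f"subject {i}: tissue probabilities do not sum to 1 in the head")
        if not (s.brainstem_mask.data > 0).any():
            raise ValueError(f"subject {i}: empty brainstem mask")


def _common_box(masks: list[np.ndarray], margin: int = 2) -> tuple[slice, slice, slice]:
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        union |= m > 0
    coords = np.argwhere(union)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + margin, union.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _extract_common(channels: dict, bs_label: VolumetricImage, box) -> dict:
    """Like extract.extract_brainstem but on a cohort-common bounding box."""
    mask = bs_label.data > 0
    offset = np.array([s.start for s in box], dtype=float)
    affine = bs_label.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ offset
    out = {}
    for name, key in (("uni", "uni_cal"), ("t1map", "t1map_cal"), ("ratio", "ratio")):
        data = np.where(mask, channels[key].data, 0.0)[box]
        out[name] = VolumetricImage(data, affine)
    out["label"] = VolumetricImage(mask[box].astype(np.uint8), affine)
    return out


def _first_pass(subjects, params: PipelineParams):
    """Stages rescale -> extract -> cluster -> match, shared by pipeline and combos."""
    validate_inputs(subjects)
    rescaled = []
    brain_masks = []
    for s in subjects:
        head = s.head_mask if hasattr(s, "head_mask") else (
            (s.tissue_probs["csf"].data + s.tissue_probs["gm"].data + s.tissue_probs["wm"].data) > 0.5
        )
        brain = s.uni.with_data(np.asarray(head).astype(np.uint8))
        brain_masks.append(brain)
        rescaled.append(
            _rescale.rescale_subject(s.uni, s.t1map, s.tissue_probs, brain, params.rescale)
        )
    box = _common_box([s.brainstem_mask.data for s in subjects])
    extracted = [
        _extract_common(r, s.brainstem_mask, box) for r, s in zip(rescaled, subjects)
    ]
    stacks = []
    for ext in extracted:
        tissue_mask = _extract.make_tissue_mask(
            ext["uni"], ext["label"], threshold=params.tissue_threshold, k=params.k
        )
        stacks.append(_extract.build_stack(ext, tissue_mask))
    return rescaled, stacks


def _cluster_cohort(stacks, params: PipelineParams, combo: str = "all3"):
    models = []
    for i, stack in enumerate(stacks):
        use = stack if combo == "all3" else stack.select_channels(COMBOS[combo])
        model = _cluster.kmeans_firstpass(
            use,
            k=params.k,
            max_iter=params.kmeans_max_iter,
            replicates=params.kmeans_replicates,
            seed=params.subject_seed(i),
        )
        model.silhouettes = _cluster.silhouette_values(use, model, seed=params.subject_seed(i))
        models.append((use, model))
    ref_model = models[params.reference_subject][1]
    matched = [
        (use, _cluster.match_centroids(m, ref_model) if m is not ref_model else m)
        for use, m in models
    ]
    return matched


def run_pipeline(subjects, params: PipelineParams | None = None, combo: str = "all3") -> PipelineResult:
    """Run the full pipeline on an in-memory cohort."""
    params = params or PipelineParams()
    rescaled, stacks = _first_pass(subjects, params)
    matched = _cluster_cohort(stacks, params, combo)

    results = []
    maps_per_subject = {}
    for i, (use, model) in enumerate(matched):
        bmaps = _cluster.labels_to_binary_maps(model, use)
        maps_per_subject[i] = bmaps
        results.append(
            SubjectResult(
                stack=use,
                model=model,
                binary_maps=bmaps,
                scale_factors={
                    "uni": rescaled[i]["factors_uni"],
                    "t1map": rescaled[i]["factors_t1map"],
                },
            )
        )

    prior_set = build_group_template(
        maps_per_subject,
        n_iterations=params.template_iterations,
        reg_params=params.registration,
    )

    for i, res in enumerate(results):
        res.priors_subject = warp_priors_to_subject(prior_set, i)
        res.segmentation = _refine.refine_subject(
            res.model, res.stack, res.priors_subject, params.p_high, params.p_margin
        )
        lsi = _evaluate.low_silhouette_index(res.model)
        mci, per_cluster, mean_w = _evaluate.missclassification_index(
            res.binary_maps, res.priors_subject, res.segmentation.distance_weights
        )
        res.report = _evaluate.QualityReport(
            input_combo=combo,
            low_silhouette_index=lsi,
            missclassification_index=mci,
            missclass_std_distance=mean_w,
            per_cluster={"missclassification": per_cluster},
        )
    return PipelineResult(results, prior_set, params)


def run_dbm(
    subjects_a,
    subjects_b,
    params: PipelineParams | None = None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    dbm_registration: RegistrationParams | None = None,
) -> dict:
    """Deformation-based morphometry between two phantom/subject groups.

    The combined cohort runs through the full segmentation pipeline; a
    second template build on each subject's six final probabilistic maps
    yields the morphometry transforms, whose Jacobian determinants are
    compared voxelwise between groups under permutation max-T FWE control.
    The analysis mask is the template region covered by any cluster.

    The morphometry registration defaults to a fluid-dominant setting
    (update smoothing only, more iterations): diffusion smoothing of the
    velocity suppresses exactly the structure-scale volume changes the
    Jacobians are meant to measure, a fidelity/robustness trade-off that
    differs from the prior-building registration.
    """
    from .dbm import dbm_group_test, jacobian_from_deformation

    params = params or PipelineParams()
    if dbm_registration is None:
        dbm_registration = RegistrationParams(
            n_demons_iterations=30, update_sigma=1.5, velocity_sigma=0.0, step=2.0
        )
    combined = list(subjects_a) + list(subjects_b)
    result = run_pipeline(combined, params)

    prob_maps = {i: r.segmentation.final_probs for i, r in enumerate(result.subjects)}
    template = build_group_template(
        prob_maps,
        n_iterations=params.template_iterations,
        reg_params=dbm_registration,
    )
    jacobians = [
        jacobian_from_deformation(template.per_subject_transforms[i], subject_id=i)
        for i in range(len(combined))
    ]
    mask = np.sum([p.data for p in template.priors], axis=0) > 0.1
    n_a = len(list(subjects_a))
    test = dbm_group_test(
        jacobians[:n_a],
        jacobians[n_a:],
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
        mask=mask,
    )
    return {
        "pipeline": result,
        "dbm_template": template,
        "jacobians": jacobians,
        "mask": mask,
        **test,
    }


def run_input_combo_experiment(
    subjects, combos=None, params: PipelineParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Repeat clustering + priors + evaluation per channel combination.

    Returns the performance table (one row per combo with the three indices
    averaged over subjects) and a dict of per-combo PipelineResult.  Paired
    tests compare each combo against "all3" across subjects.
    """
    params = params or PipelineParams()
    combos = list(combos) if combos is not None else list(COMBOS)
    runs = {c: run_pipeline(subjects, params, combo=c) for c in combos}

    rows = []
    for c in combos:
        rep = runs[c].cohort_report()
        row = {
            "input_combo": c,
            "low_silhouette_index": rep["low_silhouette_index"].mean(),
            "missclassification_index": rep["missclassification_index"].mean(),
            "missclass_std_distance": rep["missclass_std_distance"].mean(),
        }
        if c != "all3" and "all3" in runs and len(subjects) >= 3:
            base = runs["all3"].cohort_report()["missclassification_index"].to_numpy()
            other = rep["missclassification_index"].to_numpy()
            try:
                _, p, test = _evaluate.group_compare(other, base, paired=True)
            except ValueError:
                p, test = float("nan"), "degenerate"
            row["p_vs_all3"] = p
            row["test_vs_all3"] = test
        rows.append(row)
    return pd.DataFrame(rows), runs
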