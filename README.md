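# bstemseg

Segmentation of internal brainstem structures — nuclei, tracts and the
CSF/tissue boundary — from MP2RAGE-derived MRI, for neuroimaging researchers
studying brainstem anatomy and its degeneration (aging, Parkinson's and
Alzheimer's disease, SUDEP risk).

The brainstem's small nuclei and densely packed fiber tracts are invisible to
conventional T1-weighted segmentation. The MP2RAGE sequence provides two
co-registered views of the same anatomy — a bias-reduced T1-weighted image
(UNI: white matter bright, CSF dark) and a quantitative T1 relaxation map
(T1map: white matter dark, CSF bright) — whose complementary contrasts, taken
together, separate six brainstem tissue types.

## Method

1. **Anchored rescaling.** Per subject, the histogram modes of
   high-confidence (p > 0.9) white-matter and CSF voxels are mapped linearly
   onto fixed references Ref1 = 100 and Ref2 = 20:

   UNI_cal = UNI · UNIfact − UNIshift, with
   UNIfact = (Ref1 − Ref2) / (wm_mode − csf_mode) and the shift chosen so that
   wm_mode → Ref1 and csf_mode → Ref2 exactly (the T1 map maps the other way
   round: wm → Ref2, csf → Ref1). Vessel outliers are excluded from the mode
   estimate (above the 95th percentile for UNI, below the 1st for T1map);
   voxels pushed negative are repaired from their 6-connected neighbours.
2. **RATIO image.** The voxelwise quotient UNI_cal / T1map_cal further
   amplifies gray/white contrast; super-99th-percentile outliers are repaired
   from sub-percentile neighbours.
3. **First-pass clustering.** The three channels, restricted to a
   brainstem/thalamus mask and z-scored, feed k-means (k = 6, squared
   Euclidean, k-means++ with many replicates). Cluster numbering is
   harmonized across subjects by Hungarian matching of centroids to a
   reference subject.
4. **Probabilistic priors.** Every subject's six binary cluster maps are
   registered jointly to an evolving group average by diffeomorphic
   (stationary-velocity, log-demons) registration; the converged averages are
   per-cluster probability priors, projected back into each subject through
   the inverse transforms.
5. **Refinement.** A voxel whose cluster disagrees with the prior argmax is
   reassigned when prior evidence is strong (alternate prior ≥ 0.75, or
   margin ≥ 0.20). Final probabilities are prior × standardized
   centroid-distance weight.
6. **Quality and morphometry.** Low-silhouette and miss-classification
   indices quantify segmentation quality; Jacobian determinants of the
   template-building transforms support voxelwise deformation-based
   morphometry with permutation max-T family-wise error control.

A built-in phantom generator produces multi-subject MP2RAGE-like brainstem
cohorts with known ground truth (six tissue classes, Rician-capable noise,
residual bias fields, smooth invertible inter-subject warps, optional planted
atrophy), so the entire pipeline is testable without any data download.

## Worked example

```python
from bstemseg import PhantomSpec, generate_cohort, PipelineParams, run_pipeline

cohort = generate_cohort(PhantomSpec(seed=1), 4)          # 4 synthetic subjects
result = run_pipeline(cohort, PipelineParams(seed=2, kmeans_replicates=10))
print(result.cohort_report().round(3).to_string(index=False))
```

prints one quality row per subject:

```
input_combo  low_silhouette_index  missclassification_index  missclass_std_distance
       all3                85.285                     1.727                   0.781
       all3                86.110                     1.578                   0.771
       all3                82.927                     2.165                   0.797
       all3                88.058                     1.445                   0.703
```

`low_silhouette_index` is the mean percentage of voxels per cluster
(partial-volume cluster excluded) whose silhouette exceeds 0.6 — higher means
cluster assignments are well supported in feature space.
`missclassification_index` is the mean percentage of first-pass voxels
falling outside their own cluster's prior thresholded at 0.3 — lower means
fewer spatially implausible assignments. The per-subject scale factors are
logged too; for this phantom, subject 0 gives

```
UNI scale factors: fact=0.0388 shift=19.01 (wm mode 3071, csf mode 1006)
```

and the final segmentation recovers the ground truth with per-class Dice
0.988–0.998. The same pipeline is scriptable from the shell:

```bash
bstem phantom --subjects 4 --seed 1 --out cohort/
bstem run --config config.yaml          # rescale -> cluster -> priors -> refine
bstem combos --config config.yaml       # channel-combination experiment
bstem dbm --config config.yaml          # deformation-based morphometry
```

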