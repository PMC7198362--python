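# Methods

## Model and assumptions

The pipeline assumes three co-registered per-subject inputs on a common
grid: a bias-corrected MP2RAGE T1-weighted image (UNI), a quantitative T1
relaxation map, and CSF/gray/white tissue probability maps plus a binary
brainstem/thalamus label. Preprocessing (bias correction, tissue
segmentation, spatial normalization) is an input contract: the package
validates it (common grids, tissue probabilities summing to 1 over the head)
but does not perform it, since any standard structural pipeline provides it.

The segmentation model is intensity-driven with a spatial correction: six
tissue classes are assumed to be separable in the joint (UNI_cal, T1map_cal,
RATIO) feature space after per-subject intensity anchoring, and spatial
priors built from the cohort itself resolve the residual voxelwise
ambiguity. No anatomical atlas is used anywhere.

### Intensity anchoring

For each modality the white-matter and CSF histogram modes (over voxels with
tissue probability > 0.9, vessel tails excluded) are mapped linearly onto
Ref1 = 100 and Ref2 = 20. The shift is implemented in signed form,

  shift = (csf_mode·Ref1 − wm_mode·Ref2) / (wm_mode − csf_mode)   (UNI),

which makes both anchor identities exact by construction; the analogous
expression with the roles of the anchors exchanged is used for the T1 map.
Negative voxels created by the shift are replaced by the mean of their
non-negative 6-connected in-mask neighbours in a single pass over the
original values; a voxel with no qualifying neighbour becomes 0. The RATIO
image divides the two calibrated images with the denominator floored at
10⁻⁶ of its masked median, then replaces super-99th-percentile voxels by the
mean of their at-or-below-percentile 6-neighbours (no qualifying neighbour:
the percentile value itself).

"First-order neighborhood" is read as 6-connectivity throughout. Histogram
modes use 256 equal-width bins over the included range, argmax bin centre,
ties toward the lower bin. The vessel-percentile exclusion is applied within
each tissue's high-probability voxel population separately.

### Clustering and harmonization

The per-voxel channel triplets inside the brainstem tissue mask (bs_UNI >
10, i.e. half the dark anchor — a value that removes residual CSF-adjacent
near-zero voxels while keeping the boundary shell; configurable) are
z-scored per channel with the sample standard deviation (n − 1, the MATLAB
`zscore` convention) and clustered by k-means: k = 6, squared Euclidean
distance, Lloyd iterations capped at 1000, k-means++ initialization, best of
100 replicates by inertia (replicates reducible in config; the solver
relocates empty clusters, so k nonempty clusters are guaranteed). Cluster
numbering is arbitrary per subject, so centroids are matched to an
explicitly designated reference subject (default: the first) by the
Hungarian algorithm on centroid distances. Stored voxel-to-centroid
distances are plain Euclidean; the downstream weighting min-max-rescales
them per cluster, for which any monotone transform is equivalent.

### Template building and priors

Each subject's six binary cluster maps — plus an implicit background channel
1 − Σ maps that stabilizes the outer boundary — are registered jointly to an
evolving average: average, register every subject to the average, re-average
the warped maps, three outer iterations by default. The registration is a
multi-channel log-demons scheme: a bounded demons force (least-squares
combination across channels), Gaussian-smoothed (fluid σ = 1.0 voxel),
accumulated into a stationary velocity field that is itself smoothed
(diffusion σ = 1.5 voxels), 10 demons iterations per outer pass, step 2.0.
The exponential map (scaling and squaring) guarantees invertibility; the
inverse is the exponential of the negated velocity, so forward∘inverse
deviates from identity only by interpolation error (measured ≪ 0.5 voxel
RMS). On non-finite cost or a folded exponential the step size is halved
once before failing. All channels are weighted equally.

The converged channel averages are the priors; the per-subject inverse
transforms project them into subject space (trilinear, clipped to [0, 1]).

### Refinement

A voxel whose k-means label differs from the subject-space prior argmax is
reassigned to the argmax cluster iff that prior ≥ 0.75 or exceeds the
original cluster's prior by ≥ 0.20 (both bounds inclusive; argmax ties break
toward the lower cluster index). One pass only. Distance weights are
recomputed for moved voxels against their new centroid, keeping the weight
semantics tied to final membership. Final probabilities are
[label = c] · prior_c · weight — "weighted by" is interpreted as
multiplication — so exactly one channel is nonzero per voxel and never
exceeds the warped prior.

### Quality indices

The low-silhouette index averages, over the five non-partial-volume
clusters, the percentage of voxels with silhouette strictly above 0.6. The
miss-classification index averages, over nonempty clusters, the percentage
of first-pass voxels whose own-cluster prior is below 0.3 (≥ 0.3 counts as
inside). Cohort tables average subject-level indices (subjects first, then
the mean — not pooled voxels). Silhouettes above 2·10⁵ voxels are computed
on a seeded subsample. Group comparisons gate a t-test behind Shapiro–Wilk
normality at α = 0.05 (rank tests otherwise: Wilcoxon signed-rank paired,
Mann–Whitney U unpaired), with Benjamini–Hochberg FDR at q = 0.05 across ROI
families.

### Deformation-based morphometry

A second template build on the six final probabilistic maps provides the
morphometry transforms. Jacobian determinants of the forward map
x ↦ x + u(x) (central differences, one-sided at the boundary, spacing in
mm) are dimensionless volume-change ratios; values above 1 mean the subject
is locally larger than the template, so group-level volume loss appears as
determinants below the comparison group's. Group inference is a voxelwise
pooled-variance two-sided t statistic with family-wise error controlled by
a permutation max-T null — exact (fully enumerated assignments) when the
assignment space is no larger than the requested permutation count, seeded
random assignments otherwise. Permutation max-T replaces parametric
random-field FWE deliberately: it is assumption-free and verifiable at
phantom scale.

The morphometry registration defaults differ from the prior-building
defaults (30 demons iterations, fluid σ = 1.5, **no** diffusion smoothing,
step 2.0): diffusion regularization of the velocity field suppresses
volume changes at the few-voxel scale of brainstem structures — precisely
the signal Jacobians must carry. With these settings the measured Jacobian
contrast of a planted 0.7-scale atrophy is about 0.82 (atrophic/control),
i.e. roughly two-thirds of the log-volume effect, which is ample for
group detection; the smoother prior-building setting is kept where
robustness against first-pass label noise matters more than deformation
fidelity.

## The phantom: what it emulates, and what it does not

The generator builds a stylized head (CSF shell, gray/white compartments)
containing an elongated tapered brainstem cylinder whose interior holds
paired ventral tracts (label 3), paired dorsolateral tracts (label 5), a
dorsal periaqueductal-like column (label 4), a chain of nuclei blobs
(label 6) and surrounding gray matter (label 1), with a one-to-two-voxel
partial-volume shell (label 2) on the surface. It reproduces the
*statistical* structure the method depends on — the three-class intensity
ordering of each modality (UNI: csf < gray < white; T1 map reversed),
additive noise (Gaussian by default, Rician optional — at brainstem SNR the
Gaussian approximation is adequate), a smooth multiplicative residual bias
field, smooth invertible inter-subject warps, and optional volumetric
atrophy of one structure — but not anatomical realism, pulse-sequence
physics, or spatially correlated noise.

Default study conditions (frozen): grid 48×56×40 voxels at 1 mm isotropic;
per-channel noise sd 60 raw units, giving contrast-to-noise ≈ 3–4 for the
hardest class pairs (a moderate, realistic regime); residual bias amplitude
3 % (the inputs are bias-corrected by contract, so only a residue remains);
subject jitter 1.2 voxels RMS. Two class pairs are deliberately ambiguous on
a single channel (labels 1/4 share the UNI mean; labels 3/5 are close on
both raw channels) while jointly separable — the property that makes
three-channel clustering demonstrably better than single-channel clustering
on these phantoms, mirroring the motivation for using all three images.
Passing tests on these phantoms shows the pipeline's machinery is correct
under the stated statistical model; it does not certify performance on real
anatomy, scanner-specific artifacts, or pathology.

## Numerical choices and degenerate inputs

- Division guard in RATIO: ε = 10⁻⁶ × masked median of the denominator.
- Mode estimation requires ≥ 100 qualifying voxels per tissue (else an error
  naming the tissue — the upstream tissue map is unusable).
- The clustering mask must hold ≥ 50·k voxels.
- A cluster with all-equal centroid distances gets weight 1 everywhere.
- Singleton-cluster silhouettes are 0 by convention.
- Empty clusters are excluded (and logged) from index means.
- Identical groups short-circuit the paired comparison to p = 1.

## Problem sizes

Tests and the acceptance suite run cohorts of 8 subjects (16 for
morphometry) on the default 48×56×40 grid with 10 k-means replicates and
3 template iterations, and smaller 32×40×28 grids for unit-level checks —
sizes chosen so the full suite completes in minutes while every stage runs
at realistic voxel counts (≈ 7,000–8,500 brainstem voxels per subject,
comparable to a real 1 mm brainstem). The morphometry null check
re-randomizes one 16-subject null cohort into 20 seeded 8/8 splits, which
tests the family-wise error property exactly under exchangeability without
re-simulating 20 cohorts.

## Known limitations

- The demons registration recovers ~60–70 % of a planted log-volume change;
  morphometry is therefore conservative (attenuated effect sizes), not
  anticonservative.
- Priors are cohort-specific; small cohorts yield noisy priors and the
  refinement rules then rarely fire.
- The k-means global optimum is not guaranteed to coincide with the
  generative partition at low contrast-to-noise; at CNR ≲ 2.5 per channel
  classes merge and the quality indices degrade accordingly (by design this
  is visible in the miss-classification index).
- ROI delineation is accepted as input; the package only extracts ROI
  statistics.
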