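# Methods

## Problem and pipeline

`ctta` quantifies the spatial heterogeneity of lesions on contrast-enhanced
CT and asks whether heterogeneity separates two patient groups (here labeled
`low` and `high`, after the low/high nuclear-grade dichotomy in renal-cancer
imaging).  The analysis chain is:

1. **Channels.** Each volume is expanded into three channels: unfiltered,
   fine Laplacian-of-Gaussian (LoG, σ = 1.0) and coarse LoG (σ = 2.5).  The
   LoG is a band-pass: small σ passes fine texture, large σ coarse texture,
   and the Gaussian envelope suppresses photon noise.
2. **Features.** Over the lesion mask of each channel, five first-order
   histogram features: mean gray intensity, sample SD, histogram entropy,
   skewness and kurtosis.
3. **Inference.** One two-sided Welch t-test per (phase × feature × filter)
   cell — 30 cells with two phases — with Benjamini–Hochberg FDR adjustment
   over the joint family, significance at adjusted p < 0.05.
4. **Operating points.** FDR-significant cells get an empirical ROC (high
   grade positive), trapezoidal AUC, and a Youden-optimal cutoff.

## Conventions the numbers depend on

These choices are not forced by the mathematics, so they are fixed,
documented, and logged in every run's `provenance.json`:

* **LoG sigma units**: voxel units of the in-plane grid (configurable to mm
  with per-axis anisotropy correction).
* **Filter mode**: 2D per axial slice by default — 3 mm slices are thick
  relative to σ = 1.0, and per-slice filtering is the classic CT
  texture-analysis convention.  3D is available by flag.
* **Kernels**: analytically sampled Gaussian and second-derivative kernels
  with continuous normalization, truncated at 6σ, reflect boundary.  The 6σ
  truncation keeps the truncated second-derivative kernel summing to ≈ 0
  (relative DC leak < 1e-6), so constant images map to ≈ 0 and the impulse
  response equals the sampled analytic LoG kernel; at the more common 4σ
  truncation the DC residual is ~1e-4, visible as a spurious offset on
  bright constant regions.  No σ² response normalization.
* **Filtering before masking**: channels are computed on the full grid;
  the mask is applied only at feature extraction, so boundary voxels see
  their true context.  Filtered masked means can legitimately be negative.
* **Entropy**: Shannon entropy in bits over a 256-bin histogram spanning the
  per-ROI min–max range; empty bins contribute zero.  Per-ROI ranging makes
  entropy invariant under affine intensity rescaling and well-defined for
  signed, unbounded LoG responses.  Bounds: 0 (degenerate) to
  log2(256) = 8 (uniform occupancy).
* **Moments**: sample (n−1) SD; skewness = third standardized moment;
  kurtosis = fourth standardized moment in the *non-excess* convention
  (Gaussian → 3), without small-sample bias corrections.  A constant ROI
  reports sd = 0, entropy = 0 and missing (0/0) skewness/kurtosis.
* **Test variant**: Welch (unequal variances) by default; pooled Student by
  flag.  With equal group sizes the two t statistics coincide.
* **FDR family**: all tested cells jointly (30 with both phases); cells with
  fewer than two usable values per group are excluded and shrink the family.
* **ROC orientation**: high grade is the positive class; if the feature is
  lower in high grade (entropy is), scores are negated so AUC ≥ 0.5 and the
  flip is recorded as `positive_direction = high-grade-low-values`.
* **Cutoff**: maximizes Youden's J; reported as the midpoint between the
  adjacent observed feature values; J-ties resolve to the candidate nearest
  the midpoint of the group medians.
* **ROI superposition**: two readers' masks are combined by voxelwise union
  by default (keeps the heterogeneous periphery); intersection by flag.

## The phantom generator

The generator emulates the *statistical structure* the analysis assumes, not
CT physics.  Per subject and phase it writes a NIfTI volume/mask pair on a
3 mm-slice grid; defaults: 64×64×24 voxels at (1, 1, 3) mm, group sizes
77/54, ellipsoidal lesions with semi-axes drawn from 12–20 mm (the minimum
guarantees the ≥ 7-axial-slice inclusion rule by construction; generation
fails loudly if a mask ever violates it).

A lesion is: group/phase mean enhancement + correlated texture +
(optionally) a necrotic core + global i.i.d. Gaussian noise (SD 5 HU).

* **Texture field**: white noise smoothed by a Gaussian of the group's
  correlation length (default 1.5 mm), then rescaled so the *masked* texture
  SD equals the target (default 35/30 HU low/high).  Smoothing-then-rescaling
  decouples amplitude (drives the SD feature) from correlation length
  (drives the fine-vs-coarse LoG response).
* **Heavy-tail modulation — the heterogeneity knob.**  The field is
  multiplied by `exp(g·m)` with `m` a smooth unit-variance field (6 mm
  scale) and `g` drawn once per subject from a group-specific truncated
  normal (defaults 0.2 ± 0.1 low, 0.8 ± 0.3 high).  Rationale: with purely
  Gaussian fields, min–max-binned entropy is affine-invariant, so *no
  amplitude parameter can move entropy*; what entropy responds to is tail
  weight — focal hot/cold spots widen the histogram range while the mass
  stays concentrated.  Drawing `g` per subject also reproduces a striking
  property of real lesion cohorts: within-group kurtosis varies wildly
  (kurtosis is exponentially sensitive to tail weight) while entropy stays
  tight, which is why entropy survives FDR correction when kurtosis does
  not.
* **Necrotic core**: a concentric ellipsoid covering the group's necrosis
  fraction of lesion volume (defaults 5%/25%), set uniformly to
  mean − 45 HU before noise.  Liquefied necrosis is nearly homogeneous, so
  the core concentrates the histogram and lowers entropy — the mechanism
  proposed for the lower entropy of high-grade tumors.
* **Phases** share all texture parameters and the subject's tail draw and
  differ only in mean enhancement; each phase has its own field realization
  (no cross-phase texture coupling is claimed by the source study design).
* **Determinism**: every subject draws from `SeedSequence([seed,
  crc32(subject_id)])`, so identical (spec, seed) reproduce byte-identical
  volumes and growing the cohort never reshuffles existing subjects.

`heterogeneity_contrast_spec()` builds the validation cohort: groups
identical in enhancement, texture SD, correlation length and necrosis (0),
differing *only* in the tail-modulation distribution.  `null_spec()` removes
every group difference while keeping the labels.

What the phantom does **not** model: beam hardening, reconstruction kernels,
partial-volume effects at the manually-traced boundary, enhancement
kinetics, inter-reader delineation variability, or any calibrated
correspondence to real tumor texture.  Passing the recovery tests therefore
shows the *pipeline* detects the kind of heterogeneity difference it was
built for at realistic effect sizes and n — not that real cohorts carry that
difference.

## Validation strategy and problem sizes

The oracle tests pin each computational primitive against an independent
route: direct-formula moments and exact bin counts for the features,
brute-force spatial convolution with the sampled analytic LoG kernel
(reflect padding) for the filter, O(n²) Mann–Whitney pair counting for AUC,
and an independent step-up implementation for BH.

The end-to-end Monte-Carlo uses 50 heterogeneity-contrast and 50 null
replicates at n = 40 + 40 subjects on 64×64×24 grids — sizes chosen so the
whole suite runs comfortably on a single CPU while keeping per-cell voxel
counts (~3–8 k) in the regime of real ROIs.  Expected behavior, verified by
the suite: the four filtered-entropy cells are FDR-significant with
AUC > 0.7 in ≥ 90% of contrast replicates; entropy carries the smallest
adjusted p; null cohorts return an empty significant set in ≥ 90% of
replicates.

A known limitation: a cohort in which *only* entropy differs is not
constructible — an entropy shift under min–max binning mathematically
requires a tail-shape change, which the kurtosis feature also detects at
ROI-sized voxel counts (raw p typically 10⁻³–10⁻⁵ here).  Kurtosis cells
therefore co-appear in the significant set of the contrast cohorts; the
suite asserts entropy's primacy (always significant, top-ranked) rather
than exclusivity.

## Degenerate inputs and numerical edges

Empty masks and single-voxel masks are rejected at extraction (sd/skewness/
kurtosis undefined); constant ROIs report missing skewness/kurtosis rather
than a silent 0; a min = max histogram has entropy 0 by definition; cells
that lose one group entirely are excluded from the BH family with a
warning; ROC requires both classes and ≥ 2 distinct scores.  Subjects whose
extraction fails for any phase are dropped wholesale (with a logged reason)
so per-subject balance is preserved.
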