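# Methods

This note documents the models, the synthetic data regime, the numerical
choices, and the limitations of the `adpn` pipeline. It is the design record
for maintainers; the README covers usage.

## Overview of the procedure

The pipeline derives a disease-specific metabolic brain network from
volumetric PET-like images and characterizes it in five stages:

1. **Preprocessing.** Images (already in a common space) are optionally
   smoothed with an isotropic Gaussian kernel specified as FWHM in mm and are
   intensity-normalized by the mean over a designated reference region
   (classically the cerebellum), making voxel values dimensionless ratios
   with the reference mean at 1.
2. **Case/control classification.** A compact 3D residual CNN is trained to
   separate patient scans from control scans under a subject-independent
   80/20 split, with the comparison group matched to an equal number of
   scans. A linear SVM on atlas ROI means is the conventional baseline.
3. **Explainable network derivation.** Gradient-weighted class-activation
   maps are computed per scan against a fixed target class (the disease
   class): per-channel weights are the spatial means of the gradient of the
   class score with respect to the final convolutional layer's activations;
   the map is the rectified channel-weighted activation sum, trilinearly
   upsampled to scan resolution. The mean map value within each atlas region
   is that region's *local expression score*. Regions whose scores are
   significantly higher in the patient group (two-sided Welch t, Bonferroni
   over regions, P < 0.05, training set only) form the disease network. The
   composite network score of a scan is the mean local score over the
   network's regions, z-scored against the training controls.
4. **Downstream analyses.** The composite score is tracked longitudinally
   (GLM with subject blocking and categorical timepoint; paired
   follow-up-vs-baseline contrasts, Bonferroni over contrasts), regressed
   against clinical severity (half-split linear prediction of CDRSB;
   Pearson correlation of predicted score with CDRSB and MMSE), and used to
   discriminate psychotic from non-psychotic patients with a 5-fold,
   subject-stratified SVM against an ROI-feature baseline.
5. **Network organization.** Within the selected node set, between-subject
   Pearson correlation of regional activity defines each group's adjacency
   (entrywise median over 100 subject bootstraps). Connection changes
   between groups are gated on magnitude (|r| >= 0.6 with that correlation
   itself significant, |Δr| > 0.2), tested by permutation (default 1000
   shuffles of subjects between groups), and validated on bootstrap
   replicate pairs. Graph metrics (mean degree 2E/N, average clustering,
   characteristic path length over connected pairs, small-worldness against
   degree-preserving randomizations) are swept over binarization thresholds
   r = 0.30 … 0.60 in 0.05 steps, with a group-by-threshold GLM and post hoc
   Bonferroni t-tests.

## The classifier

The published deep-learning approach in this literature adapts a 101-layer
2D residual network with transfer-learned initialization to 3D volumes. That
is not reproducible at desk scale, and no public 3D initialization exists,
so the package's classifier is its own compact design, written in numpy with
explicit backward passes (the saliency analysis needs exact activations and
gradients of the final convolutional layer):

* stem 3×3×3 convolution (default 8 channels) → ReLU → 2× average pooling;
* one residual stage (configurable depth) of blocks
  `relu(x + conv(relu(conv(x))))` whose convolutions default to 1×1×1;
* a linear readout over the *spatially resolved* final activations
  ("flatten" head; a global-average-pool head is available as an option).

Three choices depart from the classical conv→GAP→linear pattern, each forced
by the synthetic data regime and worth recording:

* **Spatially resolved readout.** A convolution-plus-GAP stack is
  translation-invariant, so it can only use features that identify a
  location by its local appearance. Real brains provide that (anatomy);
  the synthetic phantom deliberately does not. During development a GAP-head
  network remained at chance training accuracy under every learning-rate,
  depth and coordinate-channel variant tried, while a linear probe showed
  the class signal present and linearly decodable in the spatially resolved
  activations. The flatten head makes that signal reachable; on anatomy-rich
  real data a GAP head would be the conventional choice, and remains
  available.
* **Voxelwise input standardization.** Inputs are standardized per voxel
  against the training set (deviation maps), the standard representation for
  spatially normalized images; a single global scale left the optimization
  poorly conditioned.
* **1×1×1 block kernels.** With 3×3×3 block kernels the final activations'
  receptive field spans roughly two parcel diameters at the coarse map grid,
  and the class-activation maps bled saliency into neighbouring regions
  (2–4 systematic false selections). Bottleneck-style 1×1×1 block kernels
  keep the receptive field at sub-parcel scale; the stem keeps 3×3×3.

Training is Adam on softmax cross-entropy (default lr 1e-3, weight decay
1e-4, batch 8, 6 epochs, inputs block-averaged 2× from the generation grid).
Training accuracy plateaus within ~5 epochs on the separable cohorts this
pipeline targets; training far past the plateau progressively *sparsifies*
the saliency (attribution concentrates on a sufficient subset of the
informative regions), so the default stops at the plateau. Everything is
plain numpy, so training is bit-reproducible given the seed.

**Attribution ensembling.** The attribution of a single compact network is
init-sensitive: different random seeds latch onto different sufficient
subsets of the informative regions. The pipeline therefore trains a small
init ensemble (default 3 models differing only in seed), scores expression
with the entrywise mean of their per-model expression tables, and reports
classification metrics from the first (canonical) model. This is the usual
ensembling remedy for saliency instability and is unit-tested to change
nothing about any single model's contract.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every acceptance check runs under.

**Anatomy.** An ellipsoidal mask on a 48×56×48 grid of 4 mm voxels (half the
classical 2 mm common-space resolution per axis; the full grid is supported
via config) is parcellated into 95 contiguous regions by seeded Voronoi
growth with two Lloyd relaxation sweeps. The two most inferior regions are
the normalization reference (the cerebellum stand-in); they are excluded
from every effect assignment and get a small regional SD (0.01 vs 0.05) —
the stability that motivates cerebellar normalization in practice, and what
keeps normalization from injecting shared noise into all regions.

**Groups and effects.** Three groups share the anatomy: healthy elderly
controls (HEC), psychotic patients (AD+P) and non-psychotic patients
(AD−P). 20 disease regions are hypometabolic in both patient groups
(default 1.0 regional SD) and 10 psychosis regions additionally in AD+P
(default 1.5 SD). Effects scale with a per-subject latent burden
~N(1, 0.3), truncated below at 0.3 (a diagnosed case carries at least that
much pathology); controls have burden 0. Regional means also vary ±10%
across regions, so "dark region" is not itself diagnostic.

**Covariance ground truth.** Designated region pairs carry target
between-subject correlations per group (defaults: four node-disjoint edges
among psychosis regions at r = 0.7 in AD+P vs 0.3 elsewhere — the
"enhanced in psychosis" pattern — and four edges among disease regions at
r = 0.6 in controls and 0 in the patient groups — "lost in disease").
Correlations are induced by per-edge shared Gaussian factors; the loadings
are solved analytically so that the *total* correlation, including the
shared-burden contribution in patient groups, equals the target (unit tests
verify convergence within ±0.05 at n = 1000).

**Longitudinal design.** Follow-up scans at 6/12/24 months for subsets
mirroring the study (26/26/29 AD+P, 59 HEC); affected regions drift by
−0.5 regional SD/year in patient groups, controls do not drift. Subjects
keep their burden across timepoints.

**Clinical scores.** CDRSB = 0.5 + 4.5·burden + ε and
MMSE = 29 − 6·burden + ε for patients, with noise SDs solved in closed form
so the true burden–score correlation is ±0.5; controls get narrow healthy
distributions. Scores are per subject (baseline assessment) and clipped to
their instrument ranges.

**Voxel model.** Region values are painted onto the grid, independent voxel
noise (SD 0.01) is added, values are clipped positive, and the volume is
smoothed at 8 mm FWHM — after effect injection, so effects bleed across
parcel boundaries exactly as in preprocessed PET. A region-level fast path
(`simulate_roi_cohort`) draws from the same generative core without voxels,
used where statistics, not images, are under test.

**Seeding.** One global seed drives per-subject and per-scan substreams that
are stable under cohort-size changes; manifests are byte-identical across
reruns.

**What the generator does not emulate** (hence what passing tests do not
show about real data): realistic neuroanatomy and local texture; partial
volume and scanner physics; site effects; spatially diffuse pathology;
demographic or ApoE4 confounding; within-subject scan-to-scan drift beyond
the modelled progression.

## Statistical and numerical choices

* **Region selection** uses the Welch (unequal-variance) two-sample t by
  default — it reduces to the pooled form under equal variances and is safer
  under group variance differences; a flag restores the pooled form.
  Two-sided p-values, Bonferroni multiplied by the number of regions tested,
  and a direction constraint (the named group's mean must be greater).
  Zero-variance regions get p = 1 with a warning.
* **No per-map rescaling** anywhere between Grad-CAM and z-scoring: maps
  enter regional averaging in native gradient units. Min–max rescaling is
  common in saliency *visualization* but would change scores.
* **Composite scores** are z-scored against the training controls; by
  construction the training-control z-scores have mean 0 and SD 1 exactly.
  The patient-specific and control-specific region sets are selected
  independently; overlap is allowed and reported.
* **Longitudinal contrasts** use all subjects having both baseline and that
  follow-up (mirroring differing per-timepoint n), while the omnibus GLM
  uses all available rows. With two timepoints and complete data the
  omnibus F equals the squared paired t (unit-tested).
* **Clinical regression** uses plain least squares when training rows
  comfortably exceed predictors, and otherwise principal-component
  regression on the 2 leading training components — regions rival subjects
  in number in this design, a small ridge penalty demonstrably overfits
  (mean recovered r 0.30 vs 0.38 for PCR against a generated 0.5), and PCR
  is the stabilization used by the covariance-pattern regression lineage
  this analysis follows. The MMSE correlation uses the CDRSB-trained
  prediction score.
* **Psychosis prediction** re-selects key regions inside each training fold
  by default (strictly leakage-free); a fixed-selection mode reproduces the
  simpler design of one selection reused across folds. Folding is by
  subject, stratified by class, ties broken by subject-id order. If a fold
  has no Bonferroni-significant region, the top-10 regions by |t| are used
  and the event logged.
* **Edge-change criteria**: an edge is classified when (a) at least one
  group's correlation passes |r| >= 0.6 *and* its own significance test at
  the group's n, (b) |Δr| > 0.2, and (c) the permutation p (subjects
  shuffled between pooled groups, both matrices recomputed per shuffle) is
  below 0.05. Gained/lost vs enhanced/reduced depends on whether the weaker
  side also passes the presence gate; swapping the groups maps
  enhanced↔reduced and gained↔lost exactly (unit-tested). Validation:
  the fraction of bootstrap replicate pairs satisfying the same gates with
  consistent direction must reach 0.95, with a Bonferroni-corrected binomial
  test over the classified set.
* **Graph binarization** keeps edges with signed r >= threshold (positive
  connectivity, matching the positive threshold grid); `absolute=True`
  thresholds |r|. Characteristic path length on fragmenting graphs is
  computed over connected pairs with the disconnected fraction reported.
  Mean degree is the raw 2E/N (no N−1 normalization).
* **Small-worldness** σ = (C/C_rand)/(L/L_rand) against 20 degree-preserving
  randomizations. The randomizer is an in-package Maslov–Sneppen chain with
  uniform edge sampling: the networkx double-edge swap samples nodes
  degree-biased, which systematically inflated reference clustering
  (ER-graph σ ≈ 0.7 instead of ≈ 1; with the uniform chain, 0.92–1.02).
* **Smoothing** converts FWHM to σ per axis in mm (isotropic in mm under
  anisotropic voxels) with zero-padded boundaries. Background label 0 is
  excluded from all ROI statistics.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the package's
own demonstration conditions: image cohorts of 60–70 subjects per group on
the 48×56×48 grid, the saliency-recovery check at 70/70 training scans and
three cohort seeds, 100–200 simulations for calibration rates, 200
permutations in tests (1000 remains the library default), and 20 replicates
for power and recovery summaries. The full-size grid and group counts are a
config change, not a code change.

## Known limitations

* The classifier is a compact surrogate, not a reproduction of the published
  101-layer transfer-learned network; its absolute performance numbers
  characterize the synthetic regime only.
* On the phantom, ROI-mean features can outperform expression features for
  the patient-vs-patient discrimination because ROI means are the
  generative coordinates of the simulation; the published ordering reflects
  real-data properties (diffuse pathology, shared scanner covariance) the
  generator does not emulate.
* Grad-CAM resolution is bounded by the final activation grid; selection
  inherits some spatial bleed from both the 8 mm smoothing and the map
  upsampling. The 1×1×1 block kernels keep this at sub-parcel scale for the
  default geometry; substantially smaller parcels would need a finer tap.
* The permutation scheme for Δr assumes exchangeable subjects between
  groups under the null; matched designs with structured confounders would
  need a stratified shuffle.
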