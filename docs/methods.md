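# Methods

This note records the model, the procedure, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Data model and conventions

The unit of analysis is a single-channel 3D scalar volume paired with an
integer parcellation atlas of R named regions.  Volumes and atlases are
aligned purely by grid shape: the package assumes upstream preprocessing
(registration to a common space, skull stripping, cropping) has already
happened and refuses shape mismatches rather than resampling.  Atlas
background is label 0; region IDs are re-indexed internally to 1..R
(original IDs are kept for reporting).  Every volume is standardized to
zero mean and unit variance per volume; all fill values and references
downstream exploit that convention (0 is the least-informative constant on
standardized data).

Dataset splits are 70/15/15 train/val/test by default, class-balanced
within ±1 sample per split via per-class largest-remainder allocation with
rotating tie-breaks (so two balanced classes yield, e.g., 98/21/21 overall
rather than 98/22/20).  A 5-fold mode is not the default path; the mask
optimization experiments use the single split.

## Synthetic cohort

Real matched case/control MRI cohorts are access-controlled, so the
package generates its own study conditions:

* **Atlas**: nearest-seed (Voronoi) parcellation from R uniformly drawn
  seed voxels.  Voronoi rather than cubic blocks so that regions are
  irregular and erosion/dilation do non-trivial work.
* **Cohort**: class 0 = Gaussian noise (sd `noise_sd`); class 1 = noise
  plus `effect_size` added inside the union of a known subset of regions.
  Standardization happens *after* signal injection — the order real
  preprocessing has (pathology is in the raw scan) — which slightly
  attenuates the planted contrast: with the defaults below, a planted
  region's post-normalization contrast is ≈ 0.48 rather than 0.6, and
  non-signal voxels shift by ≈ −0.12.
* **Defaults (the desk-scale study conditions)**: 24³ grid, R = 20
  regions, 4 signal regions, effect_size 0.6, noise_sd 1.0, 30 volumes per
  class.  These train the CNN to convergence in ~2 minutes on one CPU
  while leaving the GA genuine pruning work (16 of 20 regions are
  uninformative).

What the generator does **not** emulate: realistic MRI contrast, atrophy
patterns correlated across regions, scanner artifacts, registration error,
or inter-subject anatomical variability.  Passing tests therefore
demonstrate the correctness and recoverability of the *method* under known
ground truth, not clinical performance on real scans.

## Classifier

The 3D CNN follows the compact whole-volume design: conv(5³, 8) →
conv(3³, 16) → conv(3³, 32), each ReLU + 2×2×2 max-pool (input dims must
be divisible by 2³); flatten (32000 features at 80³ input, 864 at 24³);
dense 1024 + ReLU; dropout; dense 2 + softmax.  Dropout uses *keep*
probability 0.5 and sits at the input and before the head only.
Convolutions are same-padding, which the unchanged spatial sizes of the
reference architecture force.

Training: Adadelta (lr 0.05, decay ρ = 0.95, ε = 1e-7), categorical
cross-entropy, batch 32, early stopping after 10 epochs without
validation-loss improvement, checkpoint = highest validation accuracy.
The full-scale schedule is ~100 epochs; the desk-scale default is 30.
The engine is pure numpy (im2col convolution; the backward pass also
yields input gradients for attribution).  One engineering choice matters
for small-sample stability: the classification head is zero-initialized,
so optimization starts from the uniform prediction (initial loss ln 2)
instead of whatever the random features imply; without it, training on
~40 samples under heavy input dropout is erratic.

Masked evaluation multiplies each volume by a binary mask with fill value
0 (configurable) before prediction; the identity mask reproduces plain
accuracy exactly.

A deterministic surrogate classifier — a threshold on the mean intensity
over a voxel set, with a logistic squashing for probabilities — mirrors
the trained network's predict/gradient interface so GA and fitness
plumbing can be tested with zero stochastic training in the loop.

## Attribution

The Shapley value of a voxel group is its average marginal contribution to
the model output over coalition orderings, with out-of-coalition groups
replaced by a reference input.  The reference defaults to the all-zeros
volume — the mean of standardized data and thus the natural "absent"
value; the training-set mean is configurable.  Implementations:

* `exact_shapley` — full enumeration over 2^M coalitions with factorial
  weights; refused above M = 20.
* `sampled_shapley` — permutation sampling; unbiased, seed-deterministic,
  error ∝ 1/√(permutations); each sampled ordering contributes one
  marginal estimate to every group, so efficiency holds exactly per
  permutation.
* `compute_heatmap` backends: `grad_input` (target-class logit gradient ×
  input; exact for linear models; the default — cheap and
  voxel-resolved), `block_shapley` (cubic blocks, default side 4, each
  voxel getting its block's value divided by the block size),
  `region_shapley` (atlas regions; exact when M ≤ 20), and `external`
  (adapter for third-party deep explainers producing the same Heatmap
  type; DeepLIFT-style explainers belong here and are deliberately not
  re-implemented).

Heatmaps explain the *predicted* class of each sample by default; a flag
restricts the explained set to correctly classified samples.

## Region scoring and chromosome encoding

score(r) = (Σ strictly positive heatmap values in r) / (n_r · max value in
r); regions whose maximum is ≤ 0 score 0.  The score lies in [0, 1], is 1
exactly for a constant-positive region, and is scale-invariant per region
(it measures how uniformly positive a region is, not its magnitude).
Floating-point overshoot above 1 is clipped.  Background voxels never
contribute.

Encoding is per-heatmap (not pooled over the cohort): ranks ascending with
ties broken by region index, percentile p = 100k/R, right-closed bands at
the scheme's breakpoints — scheme A (30, 50, 70), scheme B (40, 60, 80).
The band convention shifts at most one region per boundary; one concrete
rule is fixed for reproducibility.  The encoding is monotone: a higher
score never receives a lower gene.

## Mask morphology

Gene → operation: 0 omit, 1 binary erosion, 2 identity, 3 binary dilation,
with a 6-connected 3×3×3 cross (1 iteration) by default — the smallest
symmetric 3D element; 26-connectivity and more iterations are available.
The mask is the union of contributions: dilation may overlap neighbouring
regions and the overlap is resolved by union (region identity is not
retained in a binary mask); dilation clips at the grid boundary; erosion
may legitimately empty a thin region.  Contributions are nested in the
gene for genes 1→2→3, and gene 0 contributes the empty set.

## Genetic algorithm

Fitness = β·f1 + α·f2 with f1 the masked accuracy on the training split,
f2 = 1/(number of nonzero genes), α = 0.025, β = 0.975.  The weights are
assigned so that accuracy dominates and compactness is a mild pressure;
a `weight_pairing="literal"` switch swaps them for comparison.  Test-split
accuracy is logged per generation for reporting but never drives
selection.

Mechanics: roulette (fitness-proportional) parent selection by default,
tournament size 2 by flag; single-point crossover applied per offspring
with probability 0.4 (otherwise the offspring copies its selected parent);
single-gene uniform mutation applied per offspring with probability 0.6;
elitism 1 (making best fitness non-decreasing); population size constant.
All-zero offspring are repaired by redrawing one gene from {1,2,3}
because f2 is undefined at zero regions.  Termination: 500 generations
(full scale) or mean-fitness improvement < 0.001 between consecutive
generations; the stop rule can be disabled (`stop_tol=None`) for
experiments that need the full generation budget.

The initial population is one chromosome per heatmap (a population cap can
subsample, or pad by mutated copies).  Consensus pruning freezes regions
whose gene is 0 in at least fraction θ (default 0.5) of initial
chromosomes — and any region at 0 in every chromosome regardless of θ —
for the entire run; the surviving count is reported, not asserted against
any external value.  Fitness evaluations are cached by chromosome bytes,
which matters when the evaluator is a CNN forward pass.

Two scheme runs are intersected at the region level (nonzero genes in both
best chromosomes) to produce the final region set.

## Recovery experiment

`recovery_experiment` measures whether the pipeline finds planted truth:
cohort at the default conditions; heatmaps from the deterministic
intensity surrogate (gradient×input), so no stochastic training enters;
scheme-A encoding; consensus pruning; GA against the region-recovery
evaluator, whose f1 is the fraction of planted regions with nonzero gene
in the mask's chromosome.  Region-level selection, not voxel overlap, is
the criterion — a dilated neighbour leaking voxels into a planted region
does not count as recovering it (with voxel overlap the GA correctly
discovers the degenerate one-region solution, which is evidence the
optimizer works but not the question being asked).  The stop rule is
disabled and 60 generations are run so the compactness term has time to
prune false positives.  Across seeds the GA reliably attains recall 1.0
with precision well above 0.5 while roughly halving the active region
count.

## Desk-scale defaults and determinism

The pipeline defaults (population cap 16, 12 GA generations, 30 training
epochs) are chosen so a complete two-scheme run finishes in ~3 minutes on
one CPU; all full-scale values (population 200, 500 generations, ~100
epochs) remain available through configuration.  Every stage derives its
seed from the single pipeline seed by fixed offsets; with a fixed seed and
single-threaded BLAS, runs are bit-reproducible, and each run directory
records the seed and a configuration hash.

## Known limitations

* The numpy CNN is CPU-bound and desk-scale; training the 80³
  architecture at full cohort size is out of its intended envelope.
* Exact Shapley is limited to 20 groups; voxel-level exact attribution is
  infeasible by construction, and the voxel-resolved default backend is a
  gradient method, not a Shapley method.
* The fitness couples regions only through masked accuracy; no
  multi-objective treatment of the accuracy/compactness trade-off.
* Synthetic conclusions transfer to real cohorts only in so far as the
  additive-signal model resembles real pathology (see the synthetic
  section's caveats).
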