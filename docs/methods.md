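# Methods

This note documents the models, conventions, and numerical choices behind
`rcbp`, and what the synthetic benchmarks do and do not establish.

## Pipeline and assumptions

The pipeline assumes all inputs are already preprocessed and spatially
normalized: masks and time series share one grid (by default the 2 mm
isotropic group template, 91×109×91 voxels, origin at (90, −126, −72) mm),
and ICA-style denoising, realignment, etc. happened upstream. `rcbp` checks
conformity (shape, voxel size, origin within 10⁻³ mm) and binarity of
masks, but performs no registration. ROI masks that are not exactly binary
are rejected, not thresholded: a probability map or unthresholded atlas
almost always signals an upstream mistake the user should resolve.

The resting-state connectivity path is fixed to the order smooth →
nuisance regression → band-pass → correlation → (Fisher-Z) → (PCA), and the
order actually applied is recorded in each matrix's `transform_log`.
Correlations from zero-variance series are set to 0 (with a warning) so the
clustering never sees missing values.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| smoothing FWHM | 5 | mm | common resting-state choice; 0 disables |
| band-pass | 0.01–0.08 | Hz | standard resting-state fluctuation band |
| Fisher-Z clip | 1 − 10⁻¹⁵ | — | keeps artanh finite at r = ±1 |
| k-means restarts `n_init` | 256 | — | makes best-of-restarts effectively deterministic |
| k-means `max_iter` | 10,000 | — | convergence cap, practically never reached |
| group linkage | complete | — | conservative merges on Hamming distances |
| subsampling stride | 2, even phase | voxels | keeps every second voxel per axis |
| border removal metric | Euclidean | mm | distances taken through the affine |

Seeding: one master seed per project; the unit seed for (subject, k) is
SHA-256 of `master:subject:k` reduced below 2³¹. This makes partial re-runs,
subject subsets, and any worker count reproduce byte-identical outputs.

## Conventions chosen where more than one reading existed

* **Cube-root transform.** Streamline counts are variance-stabilized with
  the signed cube root sign(x)·|x|^⅓ (not cubing); cubing would expand,
  rather than compress, the heavy right tail of count data.
* **Band-pass filter family.** A 3rd-order Butterworth applied
  forward–backward (`sosfiltfilt`): zero phase, so filter delay cannot bias
  correlations; pass-band gain is within 5% and the stop band at twice the
  high cut is attenuated more than tenfold (verified by FFT in the tests).
* **Sparse matrix indices are 1-based** in the coordinate-list text format,
  matching the dialect of the probabilistic-tractography tools that emit
  such matrices; in-memory voxel coordinates are 0-based (i, j, k) with
  world mm positions derived through the affine.
* **Median filter neighborhood** is the full 3×3×3 box, zero-padded at the
  grid border. **Target subsampling** keeps all-even-index voxels (stride 2,
  phase 0). **Downsampling** aggregates f³ blocks by majority (≥ 50% of
  in-grid cells). **ROI upsampling** maps voxel (i, j, k) to (fi, fj, fk)
  with the voxel size divided by f, preserving each voxel's world position,
  the voxel count, and pairwise non-adjacency; the returned mapping is a
  bijection back onto the original grid.
* **PCA is fitted per subject**, never pooled: pooled fitting would leak
  group structure into individual parcellations.
* **Relabeling** is solved as an optimal assignment on the k×k contingency
  table (Hungarian method), which is exactly equivalent to exhaustive search
  over all k! id permutations; the exhaustive search is retained as an
  independent oracle and the equivalence is asserted on thousands of random
  instances rather than assumed.
* **Relabel accuracy is computed against the hierarchical reference**, not
  against the post-hoc mode, since it is defined as the quality of the match
  to the reference that drives the relabeling.
* **The hierarchical reference cut** uses a merge-count cut (`cut_tree`)
  rather than a height-threshold cut: Hamming distances take few discrete
  values, merge heights tie frequently, and a height cut can then return
  fewer than k clusters.
* **Mode ties** (no strict per-voxel majority) resolve to the smallest label
  id and are logged, making the group labeling independent of subject order.

## Degenerate inputs

Internal validity indices that are undefined or infinite by their formula —
Calinski–Harabasz with zero within-cluster scatter, Davies–Bouldin with
coincident centroids — return the documented sentinel `1e12` with a warning
instead of raising, so batch reports always complete. Cophenetic correlation
on constant distances is reported as NaN. Davies–Bouldin is computed
directly from centroid norms (not via a dot-product distance shortcut) to
keep full floating-point precision; the tests hold it to 10⁻⁹ agreement with
a brute-force evaluation of the formula.

## Synthetic cohorts: what they emulate, what they do not

`PlantedDesign` describes a ground-truth cohort: a box-shaped ROI split into
k contiguous slabs (default 10×10×5 = 500 voxels, 3 parcels), one prototype
connectivity profile per parcel (a random unit vector scaled by
`prototype_separation`, default 10), and per-subject i.i.d. Gaussian feature
noise (`subject_noise_sd`, default 1) — so the default separation-to-noise
ratio is 10 and parcel centers sit about 14 noise standard deviations apart.
The default cohort has 30 subjects and 200 target features. The BOLD
generator gives each parcel a band-limited latent signal (random-phase
sinusoids inside 0.015–0.07 Hz), ties each target voxel to one parcel, and
can inject a known linear trend plus slow drift as confounds. The labeling
generator permutes cluster ids per subject and flips a fraction of voxel
labels (default 5%).

All generators are pure functions of the design (including its seed).

What passing these benchmarks shows: the pipeline's bookkeeping (voxel
ordering, label alignment, consensus, reporting) is correct, and the
statistics behave as their formulas dictate. What it does not show: realism.
The generator has no hemodynamics, head motion, spatial noise correlation,
inter-subject anatomical variability, or gradient-like (soft-transition)
connectivity — so clean recovery here does not predict clean recovery on
real data.

### A note on model selection by Calinski–Harabasz

On the default planted cohort, group recovery (mode-consensus ARI = 1
against the planted labels) and k-selection by silhouette (maximal at the
planted k) and Davies–Bouldin (minimal) are stable across prototype draws
(12/12 random seeds in our checks). Calinski–Harabasz is structurally
marginal in this regime: with three near-equidistant prototypes, merging two
clusters halves the between-dispersion but also halves the k−1 divisor,
and the within term is dominated by the 200-dimensional noise floor, so
E[CH(3)]/E[CH(2)] ≈ 1.05; the k = 2 solution additionally overfits
high-dimensional noise. In roughly 40% of prototype draws CH therefore
prefers k = 2. This mirrors CH's reputation as only a moderate
model-selection criterion, and is why the package reports several indices
side by side instead of electing a single "optimal" k. The shipped default
cohort (design seed 0) selects the planted k by all three indices.

## Problem sizes used by the test suite and acceptance script

The end-to-end benchmark runs the full default cohort (30 subjects, 500
voxels, 200 targets, k ∈ {2..5}, 256 k-means++ restarts). Oracle-equivalence
checks use 1,000 random instances per k ∈ {2, 3, 4} (50 voxels, 5 subjects)
for relabeling and 100 random instances (n ≤ 200) for the validity indices;
metric-invariance checks use 1,000 random label pairs. Workflow
determinism/resumability runs a 6-subject, 120-voxel project serially, with
4 workers, and interrupted-then-resumed, and requires byte-identical
numeric outputs.

## Known limitations

* Native-space (per-subject mask) parcellation is out of scope; the group
  step requires a shared voxel set and is skipped otherwise.
* Tractography itself (and diffusion parameter estimation) is not run; the
  diffusion path starts from an already-computed sparse matrix.
* Surface (vertex-based) inputs are not supported — voxels only.
* The workflow engine parallelizes within one process pool; there is no
  cluster-scheduler integration.
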