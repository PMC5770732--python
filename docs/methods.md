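# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of `restconn`.

## The generative model behind the synthetic cohort

Each subject's run is

    data(v, t) = Σₖ ampₖ · mapₖ(v) · tcₖ(t) + ε(v, t),    ε ~ N(0, noise_sd²)

with `n_networks` shared spatial sources and per-subject time courses
from a stable lag-1 vector autoregression `x_t = C x_{t−1} + η_t`
(spectral radius of `C` < 1 enforced; ≥ 100 burn-in steps discarded).
Sources are spherical indicator blobs on a placement lattice, smoothed
by a Gaussian of `smooth_fwhm_mm` and normalized to unit Euclidean
norm; the lattice spacing guarantees pairwise |r| < 0.3.

Two kinds of group difference are planted, mirroring what the analysis
estimates:

* **Directed coupling.**  The control group's coupling matrix carries
  directed edges at 0.5; in the patient group two of those edges are
  weakened to 0.2 (gap 0.3).  Edges run from higher to lower network
  index, keeping both matrices triangular and trivially stable.
* **Map intensity, regional.**  Spatial z-maps are scale free, so a
  *global* per-network amplitude multiplier is invisible downstream —
  it cancels when maps are z-scored.  The planted functional effect is
  therefore regional: each network's **core** (voxels ≥ 50% of its
  peak) is scaled per subject by `1 + N(0, regional_jitter_sd)`, and
  patients receive an additional offset of `effect_gap_sd ×
  regional_jitter_sd` (default: a 1-SD gap) on three networks.  The
  core-versus-periphery contrast survives z-scoring and is what the
  voxelwise group model detects.  The global multipliers (`effect_map`)
  remain available for experiments.

Severity scores for patients are `19.1 + 5.68 · latent`, where the
latent is the standardized network-0 regional modulation mixed with an
orthogonalized noise term so the in-sample correlation equals
`severity_coupling` (default 0.8) exactly; controls score near zero.
Age and sex are drawn from matched distributions with zero true effect,
so covariate adjustment is testable as a no-op.

Defaults are scaled down from acquisition scale (12 per group, 16×16×8
grid, 150 volumes) so a full cohort generates in under a minute and the
whole pipeline runs in seconds; acquisition-scale settings (20 per
group, 64×64×36, 240 volumes, model orders 20…120) are configuration
choices, not code changes.  The default `amplitude = 5` puts blob-core
signal SD near 1.0 against `noise_sd = 0.5`, the regime in which
subject-level ICA reliably recovers the planted maps.

What the generator does **not** emulate: hemodynamic convolution,
physiological and motion artifacts, scanner drift beyond a linear
trend, spatial normalization error, and inter-subject anatomical
variability.  Passing tests therefore demonstrate the *statistical
machinery* — blind source recovery, matching, calibrated inference,
unbiased cross-validation — not robustness to those nuisances.

## Preprocessing

Minimal by design: mask (default: nonzero-variance voxels), optional
isotropic Gaussian smoothing parameterized by FWHM
(σ_axis = FWHM / (2√(2 ln 2) · voxel_size_axis); reflective boundaries
conserve total intensity on small grids), and per-voxel linear
detrending plus z-scoring (idempotent; zero-variance voxels are dropped
from the mask with a warning).  Slice-timing correction, realignment
and template registration are out of scope — the pipeline accepts
already-aligned data.

## HPM-ICA

* ICA: FastICA with logcosh (negentropy) contrast, PCA whitening and
  symmetric decorrelation; 3 restarts by default, keeping the restart
  with the highest negentropy proxy; non-convergence is flagged, never
  silent.  Maps are z-scored over the mask and sign-fixed to
  non-negative skewness.
* Partner matching: similarity is absolute Pearson correlation between
  z-scored maps.  Clusters are grown greedily from the most similar
  remaining cross-subject pair; a candidate joins only if its |r| to
  *every* current member is ≥ `match_threshold` (default 0.4), at most
  one component per subject.  On small, well-separated families this
  greedy rule coincides with the exhaustive best assignment (asserted
  against a brute-force oracle in the tests).
* Hierarchy: the same matching applied to first-level cluster
  representatives across model orders, one representative per order per
  group; groups must span a majority of the supplied orders (singleton
  representatives count only when `min_orders = 1`).  Per group the
  cluster with the highest Cronbach's alpha is selected; ties break
  toward larger membership, then lower model order.
* Cronbach's alpha uses subjects' sign-aligned matched maps as items
  and in-mask voxels as observations — the only orientation that yields
  one alpha per cluster.

## Group statistics

Voxelwise OLS with intercept, group, and optional age and sex columns;
the group-contrast t has `df = n − rank(design)`.  With covariates
omitted this reduces *exactly* to the pooled-variance two-sample
t-test.

The Monte-Carlo extent threshold draws Gaussian null volumes, smooths
them at the map smoothness, **re-standardizes over the mask** (without
this the voxel threshold would be miscalibrated after smoothing),
thresholds two-sided, and records the largest face-adjacent cluster;
the threshold k is the smallest extent with null exceedance ≤ α.
Face (6-neighbour) adjacency is the conservative connectivity choice;
positive and negative suprathreshold voxels are labelled separately.
Network (RSN) masks take the positive tail of the one-sample t map at
`mask_p`.  The severity scalar per subject is the mean component z over
the relevant surviving cluster (peak-voxel is an alternative a caller
can compute from the cluster table).

## Granger causality

GCIs come from least-squares autoregressions with intercept; series are
standardized first (the index is scale-invariant; standardization
stabilizes the regression).  The default model order is 1 — matching
the generator's lag-1 ground truth — with a BIC selector over 1..5
available (`select_var_order`).  The relay-mediated index is the
unconditional-minus-conditional difference, clipped at zero; it is
isolated behind one function so an alternative definition (e.g. the
minimum of path-segment GCIs) can be swapped.

One caveat the test suite documents: the *in-sample* GCI is strictly
positive whenever the full model nests the reduced one, even for
independent series, so a one-sample t-test of unclipped GCIs against
zero over-rejects under the null by construction.  The per-group
`mean ± sd, p` summaries are therefore descriptive; calibrated
inference lives in the between-group comparison, where the shared
finite-sample bias cancels (verified at the nominal 5% level in the
tests).

## Classification

MLDA raises pooled-covariance eigenvalues below their mean to the mean
before inversion — exactly a no-op when the spectrum is flat (then MLDA
= classical LDA, asserted to 1e-8) and a stabilizer when n < d.  The
SVM's "width 0.5" is interpreted as the kernel σ in
`exp(−‖u−v‖²/(2σ²))` (γ = 1/(2σ²) = 2); the regularization constant
defaults to C = 1.  Both are evaluated under LOOCV with per-fold
standardization and per-fold t-test selection; a fold whose selection
comes up empty keeps the single smallest-p feature so no fold trains on
an empty set.  `unsafe_global_selection=True` exists solely to
demonstrate the optimistic bias of selecting on all rows and is
regression-tested: null tables stay at chance under the fold
discipline and rise well above it when leaked.

## Pipeline

Every stage's randomness derives from the master seed via named
`SeedSequence` spawns, so re-running any stage from its persisted state
reproduces the fresh end-to-end result bit for bit.  Intermediates are
written as NIfTI/TSV/JSON (plus pickled state snapshots for fast stage
re-runs); `persist: false` turns all writing off for simulation
studies.  Only clusters with a member for every subject enter group
statistics and feature assembly; with the default SNR this is all of
them.

## Known limitations

* The partner-matching rule is greedy; pathological similarity
  structures could split a true cluster where an exact assignment
  solver would not (a Hungarian variant is a natural extension).
* The planted 1-SD regional map effect is near the detection limit of
  voxelwise p < 0.01 with 12 subjects per group, so some seeds yield no
  surviving functional cluster; classification power then rests on the
  coupling features, which carry most of the planted signal.
* The measured severity correlation is attenuated relative to the
  planted 0.8 because component maps are estimated, not observed.
* GC at TR-scale sampling measures lagged linear prediction, not
  neuronal causation; no hemodynamic deconvolution is attempted.
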