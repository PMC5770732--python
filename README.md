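# restconn

Resting-state functional and effective connectivity analysis for
case--control neuroimaging cohorts, with a fully synthetic test bed.

`restconn` is aimed at researchers who want to ask, end to end: *do two
diagnostic groups differ in their intrinsic brain networks, do they
differ in the directed influences between those networks, and do those
differences classify individual subjects?*  It implements the whole
chain as a reusable, tested pipeline and ships a cohort simulator that
plants known networks and causal structure, so every stage can be
validated against ground truth before it ever touches real data.

## What it computes

**Hierarchical partner-matched ICA (HPM-ICA).**  Each subject's 4D run
(voxels × time) is decomposed by spatial ICA, `X = S Aᵀ`, with spatial
sources `S` independent over voxels and mixing time courses `A`.
Components are matched across subjects by absolute spatial correlation
("partner matching"), yielding clusters of corresponding components; the
procedure is repeated across several model orders *N*, and for each
group of matched clusters the one with the highest Cronbach's alpha,

    α = k/(k−1) · (1 − Σᵢ var(itemᵢ) / var(Σᵢ itemᵢ)),

(items = subjects' matched maps, observations = voxels) is retained as
the most reproducible depiction of that network.

**Group statistics.**  Subjects' z-scored component maps enter a
voxelwise OLS with group, age and sex regressors.  Multiple comparisons
are controlled by a Monte-Carlo calibrated minimum cluster extent:
smoothed null volumes are thresholded at the voxel-level p and the
smallest cluster size whose null exceedance probability is ≤ α becomes
the extent threshold k.  Comparisons are restricted to network masks
from one-sample t-tests, and patient-severity scores are correlated with
cluster connectivity.

**Granger causality indices (GCI).**  For component time courses x and
y,

    GCI(x→y) = ln( σ²[y | y-lags] / σ²[y | y-lags, x-lags] ),

estimated per subject by least squares.  A relay-mediated index for a
path x → relay → y is `max(0, GCI(x→y) − GCI(x→y | relay))`, the drop in
GC when the relay's past is added to both models.  Within-group
one-sample and between-group two-sample t-tests summarize each
connection.

**Classification.**  Functional (cluster mean z) and effective (GCI)
features are combined; inside every leave-one-out fold, feature
standardization and two-sample-t selection (p < 0.05, uncorrected) are
fit on the training subjects only.  Classifiers: maximum-uncertainty LDA
(pooled-covariance eigenvalues below their mean are raised to the mean,
so `w = S*⁻¹(μ₁ − μ₂)` stays defined when features outnumber subjects)
and a Gaussian-kernel SVM, `k(u,v) = exp(−‖u−v‖²/(2·width²))` with
width 0.5.  Reported: accuracy, sensitivity, specificity, and feature
weights averaged across folds.

## Worked example

```bash
restconn all --config configs/example.yaml
```

or, from Python:

```python
from restconn.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig.with_defaults({"seed": 1,
                                                 "outdir": "runs/demo"}))
print(manifest["stages"]["ica"]["n_selected"])          # 6
print(manifest["stages"]["classify"]["mlda"])
```

On the default synthetic cohort (12 patients + 12 controls, 16×16×8
grid, 150 volumes at TR = 2 s, 6 planted networks, model orders
{6, 8, 10}) a run with seed 1 prints:

```
n_selected: 6                          # all planted networks recovered
alphas: 0.985, 0.985, 0.984, ...       # cluster reproducibility
extent_k: 10                           # MC cluster-extent threshold (voxels)
mlda: accuracy 0.958, sensitivity 1.000, specificity 0.917
```

meaning the hierarchical matching found six reproducible components
(each matching its planted source at |r| ≈ 0.95), null-calibrated
cluster filtering requires ≥ 10 contiguous voxels at p < 0.01, and
leave-one-out MLDA separates the groups at 95.8% accuracy from the
planted map and coupling differences.

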