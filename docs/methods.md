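# Methods

## Model and procedure

`gcdmap` maps directed ("effective") connectivity at the voxel level. For an
ordered voxel pair (x, y) it fits two nested autoregressions by ordinary
least squares:

    restricted:  y_t = a_0 + sum_{k=1..m} a_k y_{t-k} + e_1
    full:        y_t = a_0 + sum_{k=1..m} a_k y_{t-k} + sum_{k=1..m} b_k x_{t-k} + e_2

x Granger-causes y to the extent the full model predicts better, quantified
as F_{x->y} = ln(s_1/s_2) where s_i is the residual standard deviation —
half the log variance ratio, and always >= 0 by least-squares nesting.
Significance comes from the canonical nested-model F-test with
(m, n_obs - 2m - 1) degrees of freedom, where n_obs = T - m.

Per voxel, four density maps aggregate all significant (p < alpha,
uncorrected) influences:

* **outflow**(v) = sum over targets w of F_{v->w} · 1[p_{v->w} < alpha]
* **inflow**(v)  = the same over sources
* **total-flow** = inflow + outflow, **int-flow** = inflow − outflow

Total-flow and int-flow are derived fields of `GcdMaps`, so the map algebra
holds exactly on every run. A voxel with strongly negative int-flow is a net
causal source; strongly positive, a net causal target.

Classification has two stages. Per voxel, a linear SVM (C = 1) on that
voxel's single value is scored by leave-one-out cross-validation; voxels
above 70% accuracy are reported as face-connected clusters of at least 5
voxels. For metric combinations, per-metric maps are concatenated into one
feature table and classified by a linear SVM with recursive feature
elimination (squared-weight ranking, 10% of features dropped per iteration
by default), evaluated by stratified 5-fold outer cross-validation repeated
5 times. An inner 4-fold cross-validation on each outer training set picks
the retained feature count with the highest mean inner accuracy (ties go to
the larger count, which is more stable at these sample sizes). Accuracy,
sensitivity and specificity are computed from the pooled zero-threshold
predictions over all repeats and folds; the ROC/AUC from the pooled decision
values. The permutation test reruns the entire nested procedure under
`n_perm` random relabelings and reports p = (1 + #{perm >= observed}) /
(n_perm + 1).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `order` | 1 | VAR lag count; the predictor lag window is the full range 1..order |
| `alpha` | 0.05 | per-pair significance threshold inside the density sum (uncorrected) |
| `residual_measure` | `sd` | reading of the residual magnitude; `var` doubles every F value |
| `n_discard` | 10 | initial volumes dropped (scanner equilibration) |
| `fd_threshold_mm` | 0.5 | framewise-displacement scrub threshold |
| `head_radius_mm` | 50 | rotation-to-arc-length conversion in FD |
| `band_hz` | (0.01, 0.1) | zero-phase 4th-order Butterworth band-pass |
| `C` | 1 | SVM regularisation (fixed in both stages) |
| `threshold_pct` / `min_extent` | 70 / 5 | accuracy-map reporting threshold and cluster extent |
| `rfe_step` | 0.1 | fraction of features eliminated per RFE iteration |
| `n_perm` | 100 | label permutations |

## Preprocessing choices

The temporal chain is fixed and logged: discard → FD scrub with linear
interpolation → nuisance regression (Friston-24 motion expansion plus the
in-mask global mean) → linear detrend → band-pass. FD is the Power-style
sum of absolute backward differences of the six rigid-body parameters with
rotations converted to arc length at 50 mm; the Friston-24 expansion (6
parameters, their one-frame lags, and both squared) is used only as
regressors, since no scalar displacement is defined by a regression model.
Interpolated frames are kept in the VAR estimation rather than deleted, so
the lag structure stays contiguous. The filter is applied forward-backward
because a causal filter would shift energy across lags and bias the lagged
regressions. When no tissue masks exist (synthetic grids), the global mean
is the only tissue regressor. Whether scrubbing should precede or follow
nuisance regression is underdetermined; the order above is fixed without
claiming fidelity to any particular toolbox.

## Numerical implementation

The all-pairs computation is vectorised per target: the target's own lag
design is orthogonalised once (QR) and every source's lag block is projected
against it, giving the full-model residual sum of squares from the block
least-squares identity RSS_full = RSS_restricted − c'G⁻¹c. For order 1 this
collapses further into two V×V matrix products via partial-covariance
algebra. Both paths agree with independent per-pair OLS to ~1e-14 and cost
O(V²T); a 200-voxel, 240-timepoint subject takes ~0.05 s. Masks above
20,000 voxels are refused without `force` (the cost is quadratic in voxels);
a deterministic `downsample` thins larger masks. Near-constant voxels are
flagged degenerate and contribute zero to every density sum with p = 1.
Negative log-ratios from floating-point cancellation are clipped at 0.

The classification stages fit thousands of small SVMs, so the internal
helper fits C-SVC through scikit-learn's low-level libsvm binding on a
precomputed Gram matrix, maintained incrementally across RFE eliminations
(a rank-k downdate per iteration). Binary decision values from the raw
binding are negated to match the public `SVC` convention; a unit test
asserts equality of decision values with the public estimator, which is
also the fallback if the binding is unavailable. RFE ties are broken by
feature index (lower index survives longer). Standardisation, PCA, ReliefF
and RFE are always fitted on training rows only; a leak test verifies that
a feature discriminative only on held-out rows cannot change the inner
selection. All fold assignments and permutations derive from one integer
seed.

ReliefF (k = 5 nearest hits/misses, L1 distances on standardised features,
priors-weighted misses) is implemented here directly since no installed
package provides it; it is deterministic, with ties broken by index.

## Synthetic cohorts

The generator is the exact generative counterpart of the estimator: a
stationary VAR(1) on a voxel grid (spectral radius checked, 100-step
burn-in), with Gaussian innovations (sd 1), low-frequency drift (0.005 Hz
cosine with random phase plus a linear ramp, amplitude 1), random-walk
motion traces with occasional one-frame spikes above the 0.5 mm scrub
threshold, and Table-style demographics. The default mask is an ~208-voxel
ball in an 8×8×8 grid with 240 timepoints at TR 2 s, mirroring a 250-volume
acquisition minus 10 discarded volumes at desk scale. The self-coefficient
default is 0.6: the lag-1 autocorrelation of BOLD-like series at TR 2 s,
which also places the generated signal inside the 0.01–0.1 Hz analysis
band — with near-white dynamics the band-pass filter would discard most of
the causal signal and the benchmark would measure the filter, not the
estimator. Two-group cohorts plant 2 hubs driving 5 targets each
(10 edges, baseline coupling 0.1); group substate_B (the IED-like class,
the positive label) receives the group effect added to those entries, and
every subject's nonzero couplings are jittered (sd 0.05). Subject i uses
seed + i.

What the generator does **not** emulate: hemodynamic convolution and its
regional lag variability, spatial autocorrelation and smoothing, physiological
(cardiac/respiratory) noise, tissue-specific nuisance structure, and
scanner drift nonstationarity. Passing tests therefore show estimator and
pipeline correctness under the model's own assumptions, not robustness to
real acquisition physics.

## Problem sizes in the test suite

The calibration check uses 2,000 null replicates at T = 200; hub recovery
uses 50 seeds of 20-voxel networks; cohort-level checks use 21+21 subjects
at ~208 in-mask voxels, T = 240. The 20-seed null sweep with 100-label
permutation tests per seed runs the nested cross-validation with an RFE
elimination fraction of 0.5 (11 elimination steps instead of ~60), a
problem-size choice that leaves the selection path coarser but the
procedure identical; the strong-effect check uses the default 0.1.

## Known limitations

* Bivariate (pairwise) causality only: no conditional/multivariate variant,
  no spectral decomposition, no hemodynamic deconvolution.
* The F-test assumes white residuals; after band-pass filtering the nominal
  type-I error inside the density sum is approximate (the calibration check
  runs on unfiltered series).
* Densities sum raw-threshold significances with no multiple-comparison
  correction, by design.
* Spatial steps (slice timing, registration, smoothing) are out of scope;
  inputs must already share a grid.
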