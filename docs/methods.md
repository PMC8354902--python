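# Methods

This note documents the models implemented in `taskconn`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Task design and regressors

A trial is cue → picture → rating → fixation; two instruction conditions
(*safe*, *look*) are balanced (±1) and randomly ordered within each run.
The reference design is 4 runs × 24 trials (96 trials). Default timings —
cue 2 s, picture 6 s, rating 4 s, fixation jittered uniformly on 4–8 s,
4 s lead-in — are assumptions chosen so 24 trials fit comfortably in a
480 s run; they are exposed in `TimingConfig`. Picture-valence labels
(negative/neutral/positive/erotic) are generated for realism but collapsed
everywhere downstream.

Task regressors are picture-period boxcars per condition convolved with a
canonical double-gamma HRF (positive gamma with shape 6, undershoot with
shape 16, 1:6 amplitude ratio, unit dispersion, 32 s support, unit-peak
normalised), sampled at TR resolution with no microtime upsampling. The
convolved regressors dip slightly negative during the undershoot; the
non-negativity contract applies to the boxcars before convolution. Cue and
rating confounds are convolved the same way; six motion parameters pass
through unchanged. Regression design matrices are checked for full rank
via pivoted QR, and rank errors name the collinear columns.

## Synthetic cohort generator

Per subject and run the generator produces node × time series as

```
u_t = tonic + activation + confound leak + AR(1) noise
u_t[target] += gamma * taskreg_c(t) * u_t[source]   (phasic effects)
x_t = site_gain * u_t + site_mean
```

- **Tonic**: i.i.d. Gaussian with precision drawn once per cohort — a
  modular random graph (higher within-module edge probability, negative
  off-diagonal entries so partial correlations are positive), diagonal
  loading to a minimum eigenvalue then unit-diagonal rescaling. Every
  node is guaranteed `min_degree` within-module edges so hub effects act
  on a non-empty neighbourhood. Group tonic effects multiply the hub's
  off-diagonal row/column; positive definiteness is re-checked and
  violation is an error naming the group.
- **Phasic**: condition-gated coupling added after noise, i.e. from the
  fully observed source series. This is exactly the generative form a PPI
  regression estimates, so the injected `gamma` is recovered unbiasedly
  (the site-affine transform is absorbed by the task and source
  regressors) — making parameter recovery a sharp test.
- **Activation**: a common (group-independent) task response on the
  emotion-module nodes (amplitude 0.5), so activation regressors fit real
  structure. Note that a phasic effect whose source node is itself
  task-active induces a genuine activation change at the target (the
  coupling multiplies the source's evoked response); planted-signal tests
  that should isolate the tonic channel therefore plant tonic effects
  only.
- **Nuisance**: motion is a smoothed Gaussian random walk leaking into
  each node with small per-node coefficients identical in distribution
  across groups; cue/rating regressors leak with a common coefficient;
  AR(1) innovations (φ = 0.3, sd 0.5) are added per node.
- **Sites**: additive mean plus multiplicative gain — deliberately the
  simplest structure that dummy-regressor residualization removes exactly.
  Defaults: three sites with 240/252/252 volumes at TR = 2 s.

Defaults mirror the reference study: group sizes 51 (BPD) / 26 (CLC) /
44 (NPC), 121 nodes in five modules, 4 runs. The default configuration is
**null** (no group effects): the study's real group effects were near
zero, so the null cohort is the reference condition and non-null effect
sizes (hub multiplier 2.0, `gamma` 0.5) are arbitrary documented values
used for recovery and detection tests.

What the generator does **not** emulate: volumetric images and spatial
preprocessing, haemodynamic nonlinearity and saturation, motion spikes,
physiological (cardiac/respiratory) noise, inter-subject variability in
the connectome beyond sampling noise, and heavy-tailed BOLD artefacts.
Passing tests therefore show the estimators and the inference machinery
are correct under the stated generative model — not that real data meet
its assumptions.

## Phasic estimation

Both PPI terms enter one joint regression per (source, target) pair:
`[intercept, source, safe, look, PPI_safe, PPI_look, confounds]`. PPI
terms are formed at the BOLD level (no deconvolution — the standard choice
for blocked designs) and both factors are mean-centred before
multiplication to limit collinearity with the main effects. Order of
operations: symmetrise per run → average runs → contrast → rectify →
threshold; contrasts are formed before rectification because
`|a − b| ≠ |a| − |b|`. Proportional thresholding keeps the
`floor(q·E)` largest upper-triangle absolute weights (`E = n(n−1)/2`,
default q = 0.05 → 363 of 7260 edges at 121 nodes), ties broken by
row-major order; thresholding applies to phasic matrices only (tonic
matrices are rectified but unthresholded), exposed as a switch.

## Tonic estimation

Residuals are variance-standardised per node before the covariance is
formed, making a given penalty comparable across runs and subjects. The
graphical-lasso objective penalises off-diagonal entries only (the sum
runs over ordered pairs, matching the solver convention). The solve is a
short coordinate-descent pass (20 sweeps) followed by monotone
proximal-gradient refinement until the maximum absolute parameter change
falls below `tol` (default 1e-5, 2000-step cap); non-convergence is an
error with diagnostics. Edge support uses a 1e-8 magnitude cutoff.
`λ = 0` returns the covariance inverse directly.

BIC uses the unpenalised Gaussian log-likelihood at the solution with
`k` = number of nonzero strictly-upper-triangle entries plus the number of
nodes, `n` = timepoints — the standard glasso-BIC convention; the exact
variant in the reference implementation is unverifiable, so it is isolated
in one function (`glasso_bic`). The default grid is 25 log-spaced values
in [0.01, 1]; λ is selected per run per subject, ties to the smaller λ.

## Network measures

Weighted local efficiency defaults to the inverse-weight shortest-path
formulation (efficiency of each node's neighbour subgraph with lengths
`L = 1/w`; nodes with < 2 neighbours score 0); shortest paths use
Dijkstra. Strength is the plain row sum; participation uses all modules
present in the node→module table, with unassigned parcels collected in an
explicit fifth "other" module. Phasic measures are computed on rectified,
thresholded matrices; tonic on rectified, unthresholded ones.

## Classification

Linear SVM with cost fixed at 1; features are z-scored with
training-fold statistics only. Folds are stratified by class (required
for balanced-accuracy stability with 26-vs-51 class sizes). Inner-loop
ties in model selection go to the first model in the canonical order
(phasic safe>look, phasic safe+look, tonic — each with strength, local
efficiency, participation — then the two activation contrasts). The 95%
CI is the 2.5/97.5 percentile of the per-repetition balanced accuracies
(the repetition default is 200). AUC uses decision values pooled across
outer folds within a repetition.

Site correction regresses every feature on dummy-coded site indicators
over the full sample before CV, as the reference procedure orders it; a
within-fold variant can be obtained by calling `site_correct` on training
folds externally. A site with a single subject yields a zero residual by
construction and is warned about, not rejected.

Each permutation shuffles labels once and scores a single nested-CV pass
(repetitions = 1) — one pass per permutation keeps the 1000-permutation
default tractable and is configurable;
`p = max(#\{null ≥ observed\}/B, 1/B)`. The subsampling learning curve
repeats stratified subsamples at each size, preserving the class ratio.

## Problem sizes in tests and the acceptance script

Simulation-based checks run on scaled-down cohorts chosen once: 16 nodes
in five modules, two sites of 120 volumes, 2 runs of 6 trials, 20
subjects per group, a 10-value penalty grid, and 5/3-fold (or 3/2-fold in
the permutation-calibration loop, with a 3-model subset) cross-validation.
Recovery tests use T = 2000 (glasso support, 20 seeds) and T = 5000
(PPI coupling). The permutation calibration runs 20 replicates of
200 permutations; planted-signal detection runs 10 cohort seeds. The
structural counts (96 trials, 7260 edges, 363 retained, 11 models,
121 features) are computed at full size.

## Known limitations

- Inference on which *nodes* drive classification is heuristic: averaged
  SVM weights are not selective in the formal sense, and ranks are
  reported without uncertainty.
- Full-sample site residualization leaks a small amount of information
  across CV folds (it is how the reference procedure is ordered); under
  the null this did not inflate type-I error in our calibration, but the
  within-fold variant is the conservative choice.
- The BIC degrees-of-freedom convention and the local-efficiency variant
  are field conventions, not identities; both are isolated behind single
  functions (`glasso_bic`, `local_efficiency`) so alternatives are easy
  to swap in.
- Element-wise (7260-feature) classification is out of scope; the feature
  models are node-level by design.
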