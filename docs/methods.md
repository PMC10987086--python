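# Methods

This note documents the generative model, the analysis chain, the
defaults and numerical choices, and what the synthetic data can and
cannot establish.

## Generative observer model

An observer is a vector of channel Weber fractions
`WF_i ~ Normal(mean_wf, observer_sd)`, truncated to stay positive, drawn
independently per channel by default (`shared_observer_deviate=True`
switches to one deviate shared by all channels, making every observer's
channel profile flat; the data cannot distinguish the two at the level
of single-target marginals, only through cross-channel correlations).

Channel sensitivity is Gaussian in log2-numerosity,
`w_i(n) = exp(-log2(n/peak_i)^2 / (2 sigma^2))` with
`sigma = fwhm_octaves / (2 sqrt(2 ln 2))` — "full bandwidth" is full
width at half maximum, the convention of the channel literature, and an
octave is a log2 unit. Channel peaks are equally spaced in log
coordinates between the range extremes (`channel_peaks`); the 1-channel
model is flat (no peak, infinite width). Behaviour at a probed
numerosity handled by several channels is the normalized tuning-weighted
average `WF(n) = sum_i w_i(n) WF_i / sum_i w_i(n)`.

Trial responses follow Weber's law: a reproduced count is
`round(Normal(target, WF * target))`, floored at 1 tap (a lognormal
response option with matched coefficient of variation is available
behind `lognormal_responses`). Response durations are counts divided by
a per-observer tapping rate (defaults 6.8 Hz fast, 3.3 Hz slow, 3.5 Hz
in the duration task — typical rates for these conditions).

A realized cell-level Wf is additionally corrupted by measurement noise
`Normal(0, noise_sd)`, truncated so the Wf stays positive. Cohort
simulation offers two routes that agree in expectation (tested at 1000
observers): `mode="analytic"` adds the noise to the exact
tuning-weighted Wf; `mode="trials"` simulates `n_reps` trials, estimates
the Wf as sample SD / mean, and then adds the noise. The trial-table
generator applies the same noise to each cell's generating Wf before
drawing trials, so long-format simulated datasets carry the same three
variance sources (observer, trial sampling, measurement).

### Defaults and their calibration

| parameter | default | meaning |
|---|---|---|
| `target_set` | 8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32 | probed numerosities |
| `n_reps` | 25 | trials per cell |
| `mean_wf` | 0.176 | population mean channel Wf |
| `observer_sd` | 0.08 | SD of channel Wfs across observers |
| `noise_sd` | 0.065 | measurement noise on realized Wfs |
| `fwhm_octaves` | 1.45 (2-channel), 1.10 (4-channel) | tuning full bandwidth |
| cohort size | 30 | observers per simulated experiment |

`noise_sd` is calibrated so that the *untuned* model at these conditions
yields a mean off-diagonal inter-observer correlation of ~0.5 (measured
0.502 over 1000 simulated experiments), i.e. realistic shared-variance
levels. A first-pass analytic calibration
(`r ~ observer_sd^2 / (observer_sd^2 + noise_sd^2 + Var(Wf-hat))` with
`Var(Wf-hat) ~ Wf^2 / (2(n_reps-1))`) underestimates the estimator
variance because integer rounding of counts adds variance, most visibly
at small targets; the default was therefore set by simulation at the
study conditions.

## Preprocessing

Outlier removal converts each (participant, condition, target) cell's
responses to z-scores once — sample SD, no iteration — and drops trials
with |z| > 3 (strict inequality). Cells with zero SD have undefined
z-scores; nothing is removed there and the count of such cells is
reported. Weber fractions use the sample (n-1) SD divided by the mean of
the raw, non-standardized responses. Participants missing any target
cell are excluded from the Wf matrix: the correlation analysis needs
complete participant vectors (pairwise-complete correlation is
deliberately not used). Cells whose responses are all identical produce
a legal Wf of exactly 0 and are flagged at matrix construction.

## Covariance analysis

The correlation matrix holds the Pearson correlation (not Spearman)
between the participant-vectors of every target pair. Binning and the
unbinned slope use each unordered off-diagonal pair exactly once (55
pairs for 11 targets). Numerical distance is `|log10(a/b)|`; the six
bins have half-open edges `(0, .08) [.08, .14) [.14, .21) [.21, .29)
[.29, .39) [.39, inf)`. The slope is ordinary least squares of r on
distance; its permutation null independently shuffles each participant's
Wf vector across targets (preserving every participant's Wf multiset),
recomputes the matrix, curve and slope for (default) 10,000 iterations,
and reports per-bin means, a 95% slope band, and a two-sided empirical
p-value `(1 + #{|slope_null| >= |slope_obs|}) / (1 + n_iter)`.

## Simulation-based channel-model fitting

A candidate configuration predicts a correlation matrix as the
elementwise mean over `n_experiments` simulated cohorts (default 1000;
25 trials per cell). Fit quality against an empirical matrix is
`R^2 = 1 - SS_res / SS_tot` over the off-diagonal upper triangle, with
SS_tot about the empirical off-diagonal mean; negative values mean
"worse than the mean". The mean Wf is fixed from the data, never fitted.

The search is a fixed deterministic grid: tuning width 0.5–2.0 octaves
step 0.1 (skipped for the flat model), observer_sd 0.01–0.15 step 0.005,
noise_sd 0.0–0.15 step 0.005. All grid points reuse a single set of
pre-drawn deviates (common random numbers), so differences between
neighbouring points reflect parameters, not simulation noise; truncated
normals are sampled exactly by inverse-CDF on shared uniforms to keep
this property. Replicate recovery experiments use a documented coarse
grid (6 x 4 x 4) with `n_experiments=100`; at that setting a fit takes
about 1.5 s, so 100-cohort recovery experiments complete in minutes on
one CPU. These problem sizes are the package's defaults for replicate
experiments; single-matrix fits default to the full grid.

## Cluster and factor structure

Targets are the clustered items, each described by its z-scored vector
of participant Wfs (per-target standardization, sample SD). Linkage is
Ward on Euclidean distances. The flat cut is chosen by the inconsistency
coefficient: the threshold is set just below the maximum coefficient, so
exactly the maximally inconsistent merges are split — the smallest
partition with at least two clusters that the index supports. The
coefficient window (`depth`) defaults to 3: at depth 2 the coefficient
is bounded by (k-1)/sqrt(k) for its at-most-3-merge window (max ~1.155),
which makes interior merges tie with the root and over-splits ~25% of
well-structured cohorts, while at depth 3 the root's height jump
dominates (100/100 contiguous two-cluster recoveries on well-separated
two-channel cohorts) and permuted data still yield contiguous clusters
in under 1% of iterations. An explicit `n_clusters` (maxclust) override
is available. The contiguity control permutes each participant's Wfs
across targets, reclusters with the same rule, and reports the
proportion of iterations in which every cluster is a contiguous number
range; it reports the raw proportion, making no assumption about the
number of clusters the cut returns.

Components are extracted from the targets x targets correlation matrix
of z-scored Wfs by eigendecomposition; the number retained is the count
of eigenvalues above 1 (Kaiser criterion; no parallel analysis or scree
automation). Retained loadings (eigenvector times sqrt(eigenvalue)) are
rotated with the oblique promax method by default (orthogonal varimax
gives similar dominant structure and is exposed); rotation failures
raise an error carrying the unrotated solution. Sign indeterminacy is
resolved by making each component's largest-magnitude loading positive;
components are ordered by variance explained, which is reported from the
unrotated eigenvalues (per component and total).

Each component's loading profile is summarised by a least-squares
log-Gaussian `a * exp(-log10(n/peak)^2 / (2 width^2))` — base-10 logs,
consistent with the distance metric. Initialization: peak at the
loading-weighted geometric mean of targets (positive loadings only),
width 0.2, amplitude at the maximum loading; bounds keep the peak within
half to twice the probed range and the width in [1e-3, 10]. Negative
loadings are fitted as-is. Degenerate profiles (e.g. constant loadings)
do not raise: the fit returns `converged=False` with a large width and
an r2 near zero.

### Identifiability of component peaks

With generating channels at the *extremes* of the probed range (8 and
32), each rotated component loads highly across its whole flank: the
loading profile is a plateau, and its fitted peak sits at the flank
centre (~10 and ~25 for the 11-target set) for any bandwidth. Edge-peak
positions are therefore not identifiable from loadings restricted to the
probed range — an intrinsic property of the technique, visible in
empirical component peaks that sit inward of the range ends. Peak
*recovery* experiments consequently use channels interior to the range:
the structure-recovery condition is peaks (10, 26), full bandwidth 1.0
octaves, noise_sd 0.03 ("two well-separated channels, low noise"), under
which both component peaks land within 25% of the generating values in
100/100 simulated cohorts.

## Duration control

Duration targets are derived per participant as the mean response
duration at each number target, ordered by target; the package ships a
reference table of such targets for a nine-participant subsample
(`load_reference_duration_targets`). The duration task reuses the
number-task pipeline unchanged with `response_duration` as the response
column. Because duration targets are participant-specific, the
number-vs-duration comparison pairs stimulus levels by rank (1st…11th)
and averages each participant's Wf across levels before taking paired
differences. The formal repeated-measures test on those summaries is
left to standard tools; the package computes the paired summary it acts
on. Simulated duration reproduction defaults to a mean Wf of 0.24
(coarser than number reproduction, as measured for this task).

## What the synthetic data does and does not show

The generator reproduces the features the analysis relies on: Weber-law
trial noise with integer rounding, between-observer variability that is
correlated across targets through shared channels, cell-level
measurement noise, realistic tapping rates, and the cohort geometry
(30 observers x 11 targets x 25 repetitions). It does not model practice
or fatigue across blocks, response-time microstructure, tapping-rate
drift, vocal-suppression failures, or heavy-tailed outlier processes —
the outlier-removal stage is therefore exercised only by Gaussian tails
(~0.1–0.3% removal) rather than by true lapses. Passing recovery tests
show the chain detects and characterises channel structure *of the
assumed form*; they cannot show that human data contain such structure.

## Known limitations

- The Kaiser (eigenvalue > 1) rule is noisy near threshold: single
  cohorts generated from two broad overlapping channels occasionally
  retain three components.
- The permutation nulls treat targets as exchangeable within
  participant; they do not preserve any Weber-law dependence of Wf
  variance on target magnitude (small at these conditions).
- Model comparison is by R² on the off-diagonal upper triangle only; no
  information criteria are computed, and `n_experiments` must be large
  enough (hundreds) for grid R² differences to be meaningful despite
  common random numbers.
- The grid search is exhaustive, not adaptive; its resolution bounds the
  precision of fitted parameters (0.1 octaves, 0.005 on the SDs).
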