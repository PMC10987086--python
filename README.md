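# numchan

Individual-differences covariance analysis of numerosity-tuned
sensorimotor channels.

## The problem

When people are asked to press a key a given number of times without
counting (say, "tap 16 times" while repeating *ba-ba-ba* to suppress
verbal counting), the number of taps they produce is approximately
correct but noisy, with a precision that follows Weber's law: the
standard deviation of the reproduced count grows in proportion to the
target. The scale-free precision index is the **Weber fraction**

```
Wf = SD(responses) / mean(responses)
```

How is a symbolic target number translated into a counted sequence of
actions? One hypothesis is a bank of **channels**, each tuned to a
preferred numerosity with Gaussian sensitivity in log coordinates,

```
w(n) = exp( - log2(n / peak)^2 / (2 sigma^2) ),   sigma = FWHM / (2 sqrt(2 ln 2))
```

with FWHM (the "full bandwidth") expressed in octaves. The channel idea
is testable with the **inter-individual covariance technique**, long used
for visual channels (contrast, spatial frequency, colour, motion): if
two target numbers are handled by a shared channel, an observer who is
unusually precise at one tends to be unusually precise at the other, so
the Pearson correlation of Wfs *across observers* is high for nearby
targets and falls off with **numerical distance** `|log10(a/b)|`. An
untuned (single-channel) system predicts uniformly positive correlations
with no distance dependence.

`numchan` implements the full analysis chain for this design, for
psychophysicists running number-matching (and duration-control)
reproduction experiments:

- **`synthetic_data`** — a generative observer model: per-observer channel
  Weber fractions, tuning-weighted combination across channels, Weber-law
  trial responses, and measurement noise; cohort- and trial-level
  simulation from a single seed.
- **`preprocessing`** — z-score outlier removal (|z| > 3 within each
  participant x condition x target cell), reproduction statistics, and the
  participants x targets Wf matrix.
- **`covariance`** — the targets x targets correlation matrix, the
  six-bin correlation-vs-distance curve (bin edges 0.08 / 0.14 / 0.21 /
  0.29 / 0.39 log10 units), the unbinned OLS slope, and a
  within-participant shuffle null.
- **`channel_model`** — Monte-Carlo prediction of correlation matrices
  from 1/2/4-channel configurations and a common-random-numbers grid
  search maximising the off-diagonal variance explained (R²).
- **`structure`** — Ward/Euclidean hierarchical clustering of targets
  with an inconsistency-coefficient cut and a cluster-contiguity
  permutation control; principal components (Kaiser criterion) with
  promax/varimax rotation; log-Gaussian tuning fits to component
  loadings.
- **`duration_control`** — per-participant duration targets derived from
  the number task, the duration-reproduction pipeline, and the paired
  number-vs-duration precision comparison.
- **`cli`/`pipeline`** — a `numchan` command with subcommands
  (`simulate`, `preprocess`, `covariance`, `fit`, `structure`,
  `duration`, `run-all`, `make-figures`) over the same library.

## Worked example

Simulate a 30-observer cohort from a two-channel model (channels at 8
and 32, full bandwidth 1.45 octaves) and run the analyses:

```python
from numchan import (ChannelModelConfig, simulate_cohort, wf_correlation_matrix,
                     binned_correlation_curve, distance_slope, fit_channel_model,
                     hierarchical_clusters, factor_solution, loggaussian_fit, GridSpec)

cfg = ChannelModelConfig.two_channel()          # channels at 8 and 32, 1.45 octaves
wfm = simulate_cohort(cfg, n_observers=30, seed=6)
print("grand mean Wf:", round(float(wfm.values.mean()), 3))

corr = wf_correlation_matrix(wfm)
fit = distance_slope(corr)
print(f"correlation vs distance slope: {fit.slope:.2f} +/- {fit.stderr:.2f}")
print(binned_correlation_curve(corr).round(3))

f2 = fit_channel_model(corr, n_channels=2, search=GridSpec.coarse(),
                       n_experiments=100, seed=2)
f1 = fit_channel_model(corr, n_channels=1, search=GridSpec.coarse(),
                       n_experiments=100, seed=2)
print(f"2-channel R^2 = {f2.r2:.2f}  vs  1-channel R^2 = {f1.r2:.2f}")

clus = hierarchical_clusters(wfm)
print("clusters:", clus.clusters())
sol = factor_solution(wfm)
print("components:", sol.n_components,
      "variance explained:", round(sol.total_variance_explained, 2))
for k in range(sol.n_components):
    lg = loggaussian_fit(sol.loadings[:, k], wfm.targets)
    print(f"  component {k+1}: peak {lg.peak:.1f}, r2 {lg.r2:.2f}")
```

Output:

```
grand mean Wf: 0.186
correlation vs distance slope: -1.60 +/- 0.18
         bin  mean_r  n_pairs
0      <0.08   0.501        9
1  0.08-0.14   0.455       10
2  0.14-0.21   0.281        9
3  0.21-0.29   0.206        9
4  0.29-0.39  -0.040        9
5      >0.39  -0.081        9
2-channel R^2 = 0.81  vs  1-channel R^2 = 0.02
clusters: [[8.0, 10.0, 11.0, 13.0, 14.0, 16.0], [19.0, 21.0, 24.0, 28.0, 32.0]]
components: 2 variance explained: 0.63
  component 1: peak 10.4, r2 0.87
  component 2: peak 24.6, r2 0.91
```

Reading the output: the cohort's precision sits at a Weber fraction of
about 0.18 and its inter-observer correlations fall steeply with
numerical distance (the shuffle null's slope is centred on zero, see
`shuffle_null`). The two-channel model explains most of the correlation
structure while the untuned model explains essentially none; clustering
splits the targets into a contiguous low (8–16) and high (19–32) group;
and the two rotated components form bell-shaped loading profiles peaking
near the two flanks of the tested range.

The same analysis from a shell:

```sh
numchan run-all --trials simulate --outdir demo --seed 6
numchan make-figures --run-dir demo
```

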