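# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `duonorm`. It is written for users who want to understand
what the package computes and what the simulation benchmark does and
does not demonstrate.

## Problem setting

Dual-colour antibody microarrays measure, per spot, two fluorescence
intensities (Cy5, Cy3) of competitively bound, differently labelled
protein samples. Analysis works in MA coordinates: M = log2(Cy5/Cy3),
A = (log2 Cy5 + log2 Cy3)/2. Within-array normalisation removes the
intensity-dependent dye bias by locally regressing M on A (loess) and
keeping the residuals.

Boutique antibody arrays break the two assumptions behind plain global
loess: most features unchanged, and up/down regulation balanced. When a
large, one-sided fraction of proteins is regulated, the global curve is
dragged towards the regulated cloud and true signal is shrunk away.
The package therefore centres on *rank-invariant* probe selection: find
probes whose intensity ranks nearly agree between the channels — a
data-driven surrogate for housekeeping controls — and fit the
normalisation curve (only or mainly) through them.

## The processing chain

1. **Spot filtering.** Flagged spots get weight 0 but are never dropped,
   so probe layouts stay aligned across arrays.
2. **Background correction (`background`).** The normexp convolution
   model: observed S = B + T with B ~ Normal(mu, sigma²) background and
   T ~ Exponential(mean alpha) signal, fitted per channel by maximum
   likelihood; each intensity is replaced by E[T | S] plus an offset
   (default 50) that stabilises the variance of low intensities.
3. **Within-array normalisation (`normalize_within`).** One of:
   - **GL** — global loess, all probes weight 1;
   - **InvTseng** — iterative rank-invariant selection with boundary
     exclusion, binary weights, linear tail extrapolation;
   - **InvMod** — the modified selection (below), graded weights, no
     extrapolation needed;
   - **RDWGL** — single global loess with the graded rank-difference
     weights on all probes;
   - **NN** — no within-array normalisation.
4. **Between-array normalisation (`normalize_between`).** A-quantile:
   every array's sorted A-vector is replaced by the across-array mean of
   sorted A-vectors; M untouched; idempotent and rank-preserving.
5. **Duplicate aggregation (`arraydata.collapse_duplicates`).** Spots of
   the same antibody are averaged (default mean) after normalisation, so
   curve fitting sees all spots but testing sees one value per antibody.
6. **Differential expression (`diffexp`).** Per antibody, a two-group
   linear model with an empirical-Bayes moderated t: the variance prior
   (d0, s0²) is estimated by matching moments of log sample variances
   under the scaled-F assumption; the posterior variance
   (d0·s0² + df·s²)/(d0 + df) enters the t statistic with d0 + df
   degrees of freedom (capped at the pooled residual df). Raw two-sided
   p-values are the ranking statistic; no multiplicity adjustment is
   applied because downstream ROC analysis only uses the ordering.

## Selection algorithms

Ranks are computed per channel over the unflagged probes with
average-rank tie handling; Δ_g = |r(Cy5_g) − r(Cy3_g)|.

**InvTseng.** Initial set: Δ_g < d (default d = p·G) and average rank
strictly inside (l, G − l), defaults l = 25, p = 0.02. Each iteration
re-ranks within the current set and keeps members with Δ < p·|S|;
stops when the set size stops changing. Because the within-set
threshold p·|S| eventually admits only exact rank ties, an iteration
that would shrink the set below `min_size` (default 30, the minimum a
loess fit needs) is not applied; the previous set is kept and flagged.
Weights are binary. Since the boundary exclusion removes the intensity
extremes, the fitted curve is extended by straight lines through the
10% most extreme selected points per side.

**InvMod.** Initial set: Δ_g < p·G with no boundary exclusion, so the
extremes stay eligible and the selected set spans the intensity range.
Each iteration re-ranks within the current set and keeps the proportion
p (default 0.99) of members with the smallest Δ — a quota of
ceil(p·|S|) — stopping at the first set with at most k·G members
(default k = 0.25). The printed threshold form "Δ < p·|S|" cannot shrink
a re-ranked set for p near 1 (the largest possible Δ in a set of size s
is s − 1 < 0.99·s whenever s ≥ 100), so the proportional-quota reading
is the one implemented; it reproduces the intended behaviour of many
slow, high-retention iterations. Tie handling is deterministic: all
probes tied at the quota boundary are kept when that still shrinks the
set; if keeping them would retain every member, boundary ties are
broken by probe index; if every Δ in the set is equal (e.g. an exact
self-self array) no probe is distinguishable and the algorithm stops
with the current set. Final weights are the standardised negative rank
differences w_g = (maxΔ − Δ_g)/maxΔ over the final set (all 1 when
maxΔ = 0), 0 outside.

Note the granularity constraint: a quota of ceil(p·s) can only shrink
sets larger than 1/(1 − p) members (100 at p = 0.99). With the default
810 antibodies in duplicate the target 0.25·G ≈ 405 is well above this
floor; for very small arrays a smaller p is appropriate.

**RDWGL.** Δ is computed once over all unflagged probes and the graded
weights are applied directly in a single weighted global loess, without
selection iterations.

## Weighted loess

No installed Python smoother accepts prior observation weights, so the
package implements the classic recipe: tricube kernel over a
nearest-neighbour span (default 0.3), local linear fit, 4 Tukey-biweight
robustifying iterations; prior weights multiply the kernel, and
zero-weight probes are excluded from both the windows and the solves.
For more than 150 fit points the curve is solved at quantile-spaced
knots and linearly interpolated (median interpolation error on smooth
MA clouds is below 5e-3, an order of magnitude under the noise level).
After fitting, the curve is shifted by the weighted mean of the
residuals so that the normalised M values have exactly zero weighted
mean over the fitting probes. Loess is not exactly idempotent (the
smoother is not a projection); a second pass changes the residuals by
an order of magnitude less than the first.

Extrapolation outside the weighted support is 'none' (undefined,
NaN) for GL/RDWGL, linear tails for InvTseng, and nearest fitted value
for InvMod (whose selected support spans the range by construction).

## Normexp numerics

Given S = s the signal posterior is Normal(m*, sigma²) truncated to
t > 0 with m* = s − mu − sigma²/alpha, so E[T|S = s] =
m* + sigma·phi(m*/sigma)/Phi(m*/sigma). The ratio is evaluated through
`log_ndtr` so deep-left tails do not underflow; the closed form matches
numerical quadrature to 1e-6 relative over s in [mu − 4·sigma,
mu + 20·alpha]. The MLE runs on (mu, log sigma, log alpha) with
analytic gradients (L-BFGS-B) from a method-of-moments start, with
box bounds tied to the data scale to keep the optimiser out of
degenerate corners; a Nelder-Mead retry and finally the
method-of-moments estimate (recorded in provenance) back it up. At
n = 20,000 draws from the generative model the MLE recovers mu and
alpha to about 1% and sigma to about 2-5% (sigma carries the least
information when alpha ≫ sigma).

## The synthetic self-self baseline

The benchmark replaces a laboratory self-self reference set (same
sample in both channels; any nonzero M is technical bias) with a
generator (`simulate`). Defaults, chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_arrays | 20 | self-self arrays |
| n_antibodies × duplicates | 810 × 2 | spots per array |
| a_meanlog, a_sdlog | 2.30, 0.25 | log-normal A distribution (median ≈ 10 log2 units, range ≈ 5–18) |
| dye_bias | cubic, ≈ ±0.3 | shared smooth bias curve in scaled A |
| sd_curve | 0.50 | sd of per-array random linear/quadratic bias coefficients |
| sd_array | 0.05 | per-array constant M offset sd |
| sd_noise | 0.08 | per-spot M noise sd |
| rho_dup | 0.6 | duplicate-spot noise correlation |
| a_jitter_sd | 0.05 | per-spot A jitter across arrays |

Two design points deserve comment. First, the per-array random bias
curves (`sd_curve`) are essential: a bias curve shared by all arrays
cancels from every group contrast, so without array-to-array curve
variation non-normalised data would look deceptively competitive and
the benefit of within-array normalisation would be invisible. The
value 0.5 gives per-array curve amplitudes comparable to the spike-in
effect sizes, which reproduces the qualitative signature of real
self-self sets: decent median performance of unnormalised data with
run-to-run collapses to chance. Second, the noise scale was calibrated
so that global loess on symmetric scenarios attains median AUC ≥ 0.85
(the regime in which all normalisation methods should perform well);
both values were fixed during generator design and then frozen.

**Spike-in scheme.** Each simulation run randomly splits the arrays
into balanced 'tumour'/'control' groups, draws a fixed proportion of
antibodies as regulated (a fraction `asym` of them upward), draws one
shift magnitude per antibody from N(0.1, 0.1²) left-truncated at zero
(mean/sd parameterisation), and adds/subtracts it from the M values of
both duplicate spots on every tumour array. A values are unchanged and
intensities are rebuilt as Cy5 = 2^(A + M/2), Cy3 = 2^(A − M/2) (the
algebraically consistent inverse of M = log2(Cy5/Cy3)). The default
scenario grid: symmetric regulation at 20% and 40% DE, fully
asymmetric regulation at 10-60% DE, 100 runs each (the bundled
benchmark uses 25 runs per scenario to keep a full grid affordable on
one CPU; medians are stable at that depth, interval endpoints less so).

**What the generator does not emulate:** scanner saturation and
censoring, spatial artefacts within an array, probe-specific binding
affinities, heavy-tailed or intensity-dependent noise, and control
spots. Passing benchmarks therefore demonstrate the relative behaviour
of the normalisation methods under the modelled distortions, not
absolute performance on any particular laboratory platform.

## Evaluation

Per run, antibodies are ranked by raw moderated-t p-values against the
spike-in truth; the ROC is computed over all thresholds with ties as
midpoints, so the trapezoidal AUC equals the normalised Mann-Whitney U
statistic. Per scenario and method, runs are summarised by the median
AUC, its empirical 95% percentile interval, and a median ROC curve by
vertical averaging (median sensitivity at a fixed 101-point
specificity grid) — chosen over threshold averaging as the standard
reading of "median sensitivity and specificity".

The classifier assessment uses a nearest-shrunken-centroid (PAM-style)
model: standardised centroid differences d_ik = (x̄_ik − x̄_i)/(m_k(s_i
+ s0)) with s0 the median pooled within-class sd, soft-thresholded by
Δ; prediction by smallest standardised distance with a class-prior
term, falling back to the largest prior when every feature is shrunk
away. Δ is chosen on a 30-point grid by seeded stratified 10-fold
cross-validation (ties towards the most parsimonious Δ). Prediction
error is estimated by the .632 bootstrap (0.368·apparent +
0.632·mean out-of-bag over 100 resamples, threshold re-selected inside
every resample; degenerate single-class resamples are redrawn). The
plain .632 estimator is optimistic when the classifier can overfit
(apparent error near zero); it is reported as defined rather than
silently replaced by the .632+ variant.

## Numerical and design choices

- Strict inequalities in all selection thresholds, as defined.
- Average-rank ties everywhere ranks are used.
- Loess: span 0.3, local linear, tricube, 4 robust iterations, ≤ 150
  knots — all configurable per call.
- A-quantile ties map to the mean of the corresponding target
  quantiles; unequal defined-probe counts are handled by rank
  interpolation (with a warning) and break exact idempotence.
- Empirical-Bayes moment equations unsolvable (underdispersed
  variances) → d0 = ∞ and s0² = mean(s²), i.e. full shrinkage to the
  common variance.
- Degenerate Eq-style weight denominators (maxΔ = 0) → all selected
  weights 1: every probe is equally invariant.
- Duplicate spots are treated as independent observations during curve
  fitting and averaged afterwards; technical-replicate arrays are
  treated as independent samples in classification, which biases
  bootstrap error estimates optimistically (a deliberate, documented
  simplification).
- Background correction refuses a second application (provenance flag)
  because E[T|S] + offset is not idempotent.

## Limitations

- The rank-invariant methods assume a usable fraction of genuinely
  unregulated probes; at extreme regulation (≥ 60% one-sided) even the
  modified selection degrades, visibly in the benchmark.
- The loess engine is one-dimensional in A; print-tip or spatial
  effects are out of scope.
- Only two-group designs are supported in `diffexp`; no covariates or
  contrast matrices.
- The benchmark's absolute AUC levels depend on the synthetic baseline
  calibration; only relative statements across methods transfer.
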