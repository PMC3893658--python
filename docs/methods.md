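# Methods

This note documents the statistical models, the defaults and why they
were chosen, the numerical choices that affect results, and what the
synthetic-data generators do and do not emulate.

## Harmonic regression (cosinor) and the center of gravity

Entrained diurnal profiles are modelled with a fixed 24-h base period as

y(t) = M + Σ_{h=1..H} a_h cos(2πht/24) + b_h sin(2πht/24),  H ≤ 3,

fitted by unweighted ordinary least squares to individual replicate
observations (not per-ZT means), so time points with more animals carry
proportionally more weight. Free-period estimation is out of scope:
animals are entrained to a 12:12 light:dark cycle, so the period is
known.

Model selection is forward stepwise. The fundamental is retained only
if the F-test of the H=1 model against the intercept-only model rejects
at α (default 0.05); each additional harmonic is retained only if its
incremental F-test (2 numerator df) rejects at the same α. A profile
that fails the fundamental gate is reported as a `NoFit` with the gate's
p-value; an all-constant profile gets p = 1 by convention. The overall
F/p reported for a retained fit compares the final model to the
intercept-only model. On a k-point ZT grid, harmonic h is only
attempted when 1 + 2h ≤ k (at the 6-point, 4-h grid the third harmonic
sits at the Nyquist frequency, where its sine component vanishes and the
design becomes singular) and at least one residual degree of freedom
remains.

The **center of gravity** (CG) summarises the phase of a possibly
multi-peaked fitted curve. It is defined here as the argument of the
curve-weighted fundamental resultant,

CG = (24/2π) · arg Σ_t w(t) exp(i2πt/24),  w(t) = fitted(t) − min_t fitted(t),

evaluated on a dense grid over [0, 24) (step 0.01 h; the grid error is
far below 0.01 h). This definition was an open design choice: it equals
the acrophase exactly for single-harmonic fits (the weight function is
symmetric about the peak) and degrades gracefully for bimodal curves,
landing between the two peaks in proportion to their mass. It is
rotation-equivariant (shifting the curve by Δ hours shifts CG by Δ) and
scale-invariant. CG is undefined, and an error is raised, for a flat
curve or when the fundamental resultant vanishes (e.g. a pure
second-harmonic curve with two equal peaks 12 h apart).

The significance level is a configuration knob; 0.05 is the default
throughout. Duplicated 24-h points (ZT0/ZT24 double-plotting is a
display convention) are folded onto ZT0 before fitting.

## Bioluminescence feature extraction

Reporter traces are counts/second at uniform sampling (default 10 min)
over several days. Processing:

1. **Detrend**: subtract a centered 24-h running average. The window
   must be an integer multiple of the sampling interval; the symmetric
   window spans window/dt + 1 samples (145 points at 10-min sampling),
   which removes constants and linear drift exactly and attenuates a
   24-h harmonic to a leakage of 1/145 (~0.7%) of its amplitude. The
   half-window at each edge, where the average is undefined, is flagged
   invalid and excluded from all downstream feature extraction (the
   source texts do not state an edge rule; exclusion is the conservative
   choice).
2. **Smooth and pick extrema**: a centered 2-h moving mean suppresses
   counting noise (the valid region is further eroded by the smoothing
   half-window so the smoother never touches undefined samples); local
   maxima/minima separated by ≥ 16 h restrict detection to
   circadian-scale oscillation, consistent with the 20–28-h band used
   for rhythm detection. Each extremum is refined to sub-sample
   precision as the vertex of a quadratic fitted over ±3 h; without this
   refinement the 10-min sampling grid dominates the period error.
3. **Features**: the first-cycle peak phase is (start_zt + first peak
   time) mod 24. Amplitudes are computed on the detrended scale (raw
   vs detrended was unstated in the source method; detrended is assumed
   and flagged here): cycle-1 amplitude is first peak minus the first
   following trough, cycle-2 amplitude is second peak minus that same
   trough. The period is the mean of successive peak-to-peak intervals
   among peaks in the first 72 valid hours. A trace with fewer than two
   detected peaks is arrhythmic; the period is then undefined.

Note the true first peak of a damped cosine A·e^{−λt}cos(ω(t−t_p)) is
earlier than t_p by arctan(λ/ω)/ω (~0.15 h at λ = 0.01/h); recovery is
therefore assessed against the peak of the generating curve, not the
nominal peak parameter.

## Circular statistics

Phases are hours mod 24, converted internally to radians by 2π/24. The
circular mean and resultant length r come from the resultant of unit
phase vectors; r = 0 leaves the mean direction undefined (NaN).

The **Rayleigh test** uses z = n·r² with the standard finite-n corrected
p-value p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·r, chosen
over exp(−z) because group sizes in this setting are small (n ≈ 14–17).
A seeded Monte-Carlo p under the uniform null is available and
recommended below n = 10; at n = 8 the correction agrees with a
10⁶-draw null to within 10⁻³.

The **Mardia–Watson–Wheeler** two-sample test uses uniform scores
β_i = 2π·rank_i/N of the pooled sample (mid-ranks for ties) and

W = 2 Σ_j (C_j² + S_j²)/n_j,

with C_j, S_j the cosine/sine score sums of group j. The asymptotic
reference is χ² with 2 df; when min(n₁, n₂) < 10 a permutation p is
used instead — exhaustive over group assignments when C(N, n₁) ≤
20,000, otherwise 9,999 sampled permutations with the add-one estimator.
The exact permutation p is necessarily discrete (at 6+6 it has ~20
atoms, because W is invariant under rotations and reflections of the
rank circle); it is valid (P(p ≤ t) ≤ t) but conservative at small n.
The test errors out when all pooled observations are identical.

## JTK-style rhythm detection

Series of ≥ 8 points (typically 12 points over 44 h at 4-h sampling)
are scored against cosine templates cos(2π(t − φ)/P) for periods P over
20–28 h and phases φ over [0, P), both gridded at the sampling interval.
Agreement is Kendall's S = C − D over pairs at which the template
values differ (pairs tied in the template are removed, the standard JTK
treatment). Each template is scored one-sided for positive tau and the
p doubled; the phase grid covers the full cycle, so negative
correlation is captured by the anti-phase template — this also makes the
reported best phase the positively-correlated peak phase rather than an
arbitrary anti-phase partner.

For series of length ≤ 14 the null distribution of C given the
template's tie-group sizes is exact, computed by dynamic programming:
under the null the data are an exchangeable tie-free sequence and the
distribution of cross-group concordances factorises into a convolution
of Mann–Whitney U null distributions (the q-multinomial identity). The
DP is validated against full permutation enumeration at n ≤ 8 in the
test suite. Longer series use a normal approximation for S with the
tie-corrected variance and a continuity correction. Ties in the data
simply drop out of C and D, which makes the reported p conservative.

The raw minimum p over templates is anticonservative (a minimum over
~18 correlated tests), so the scan also reports a Bonferroni-adjusted p
over the template count; the adjusted p feeds Benjamini–Hochberg
q-value computation and keeps the noise-only false-positive rate at
α = 0.05 around 1–3% (measured over 2,000 simulations). This is a
deliberate deviation from the published scan, which reports the
uncorrected minimum; both numbers are exposed.

A clock-controlled gene (CCG) is a series with q < 0.1 **and** best
period in 20–28 h; its peak phase is binned into day (CT0–11) or night
(CT12–23), with CT treated as equal to ZT for entrained data.

## Differential-expression layer

* Per-ZT comparisons are Student (equal-variance) t-tests, matching the
  era's software default; Welch is available by flag. One-tailed tests
  are applied only at pre-registered ZTs with a stated direction. Both
  groups constant and equal gives p = 1; constant, unequal groups give
  p = 0.
* Fold-change tiers at a single-ZT screen: fc = mean(treated)/mean
  (control); "strong" = symmetric fold change ≥ 2 with p < 0.05,
  "moderate" = ≥ 1.5 and < 2 with p < 0.05. Down-regulation is reported
  as 1/fc-fold down. Boundaries are inclusive (fc = 2.0 is strong).
* Two-way ANOVA is fixed-effects Time × Treatment with Time categorical,
  via OLS with type-II sums of squares (identical to the classical
  decomposition for the balanced designs generated here). Residual
  normality is checked by Shapiro–Wilk at α = 0.05; on rejection a log
  then a sqrt transform of the response is tried in that order, keeping
  the first that passes (or the best-scoring of the three if none do),
  and the transform applied is recorded. Tukey HSD runs across all
  Time × Treatment cells; the control-vs-treated contrast within each ZT
  is reported. No variance moderation is applied (none was described for
  the original small-n microarray tests; this caveat matters at
  n = 2/group).
* Peak-to-trough amplitude: max/min of per-ZT means per series (≥ 1 by
  construction); the treated/control ratio is rounded half-up to one
  decimal, which reproduces the published amplitude-ratio table exactly
  from its printed peak-to-trough columns.

## Synthetic data: what it does and does not emulate

Replicate tables follow mean curves M + Σ A_h cos(2πh(t − φ_h)/24)
(acrophases in hours, matching ZT conventions) with **multiplicative
lognormal noise of unit median**, so values stay positive, the
replicate CV equals `noise_cv`, and the log-transform used by the ANOVA
layer is exactly normalising. Bimodal profiles are represented by a
second harmonic rather than a mixture, matching the model family used
for fitting. Parameters are validated so the mean curve stays positive.
Defaults mirror the study design: ZT0–20 at 4-h steps, 5 replicates
per cell, two treatment groups. The shipped analyte presets are
illustrative documentation fixtures encoding the qualitative published
effects (phase advance of per2/per3, damped Npas2, bimodal Cyp7a1 and
triglyceride profiles, anti-phase bile-acid and NAD/NADH rhythms), not
data.

Bioluminescence traces are polynomial drift + A·e^{−λt}cos(2π(t +
start_zt − peak_zt)/P) + Gaussian noise. The default noise scale (2
counts/s) is anchored to photon-counting statistics of a ~300 counts/s
signal integrated over 10-min bins (~0.7 counts/s), inflated ~3× for
biological irregularity. Phase samples are von Mises; κ = 0 yields the
circular uniform.

The generators do **not** emulate: probe-level microarray structure,
sequencing counts, inter-animal random effects (replicates are i.i.d.
within a cell), autocorrelated reporter noise, or explant-to-explant
damping variability. Passing tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
feature of real data.

## Problem sizes and numerical details

Calibration and recovery suites use: 500 simulations for CG recovery
(noise_cv 0.2, n = 5, amplitude/mesor = 0.5), 2,000 for the
rhythmicity-gate and ANOVA type-I errors, 200 seeded traces for
bioluminescence recovery, 10⁶ draws for the Rayleigh Monte-Carlo null,
and 2,000 noise series for the JTK false-positive rate. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are checked against. RSS comparisons in the stepwise F-tests treat
residuals below 10⁻¹⁰ of the response's sum of squares as exact fits
(F = ∞, p = 0) to keep noiseless recovery well-defined; template tie
groups are formed after rounding template values to 9 decimals; all
random number generation flows through `numpy.random.default_rng` /
`SeedSequence` so identical seeds give bitwise-identical outputs.

## Known limitations

* The CG definition is a package convention (documented above); other
  software may summarise multi-harmonic phase differently, so CG values
  are comparable within this package but not necessarily across tools.
* The cosinor gate's F-test assumes additive Gaussian noise; under the
  generator's lognormal noise at CV ≤ 0.25 the size distortion is
  negligible, but heavier multiplicative noise should be log-transformed
  first.
* JTK q-values are computed from Bonferroni-adjusted minimum p-values,
  which is conservative; rankings are unaffected.
* The MWW permutation p is discrete for very small groups; report the
  atom structure (returned in `extra`) when n ≤ 8 matters.
* No mixed-effects or repeated-measures support: every observation is
  treated as independent.
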