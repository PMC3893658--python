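# zeitgeber

Analysis toolkit for diurnal (24-h) time-course experiments of the kind
used to study the peripheral circadian clock — for example, liver gene
expression, metabolite panels and PER2::LUC bioluminescence reporting in
mice under a 12:12 light:dark cycle, sampled every 4 h with a handful of
replicates per time point. It is aimed at chronobiologists and
biostatisticians who need the full chain from raw replicate tables to
rhythm calls, phase statistics and diurnal differential expression, with
every stage testable against synthetic data of known ground truth.

## What it computes

**Cosinor fitting with harmonics** (`zeitgeber.cosinor`). Each analyte ×
treatment profile is fitted by least squares to

```
y(t) = M + Σ_{h=1..H} [ a_h cos(2πht/24) + b_h sin(2πht/24) ],  H ≤ 3
```

with a rhythmicity gate: the fundamental is kept only if an F-test
against the intercept-only model rejects at α (default 0.05), and each
extra harmonic only if its incremental F-test rejects. Profiles failing
the gate are reported as "no fit". The phase of a fitted (possibly
bimodal) curve is summarised by its **center of gravity**

```
CG = (24/2π) · arg Σ_t w(t) e^{i2πt/24},   w(t) = fitted(t) − min fitted(t)
```

which equals the acrophase for a single-harmonic fit and degrades
gracefully for multi-peaked curves.

**Bioluminescence features** (`zeitgeber.biolum`). Reporter traces
(counts/s every 10 min over ~4 days) are detrended by subtracting a
centered 24-h running average; circadian peaks and troughs of the
lightly smoothed signal give the first-cycle peak phase (mod 24 h),
cycle amplitudes (first peak − first trough; second peak − first
trough), and the period as the mean peak-to-peak interval over the first
three days. Traces with fewer than two peaks are scored arrhythmic.

**Circular statistics** (`zeitgeber.circstats`). Peak-phase samples on
the 24-h clock face: circular mean and resultant length r, the Rayleigh
uniformity test (z = n·r², finite-n corrected p, optional Monte-Carlo
null), and the Mardia–Watson–Wheeler two-sample uniform-scores test with
exact/sampled permutation p-values for small groups.

**JTK-style rhythm detection** (`zeitgeber.jtk`). Kendall-tau agreement
of a series with cosine templates over a 20–28-h period grid and all
phases; exact template-tie-aware null distribution by dynamic
programming for short series; Benjamini–Hochberg q-values; and the
clock-controlled-gene rule (q < 0.1 and period in 20–28 h) with
day (CT0–11) / night (CT12–23) peak-phase binning.

**Diurnal differential expression** (`zeitgeber.de`). Normalisation to a
reference analyte (e.g. 18S rRNA), per-ZT Student t-tests with
pre-registered one-tailed exceptions, fold-change tiers (≥2-fold and
1.5–2-fold at p < 0.05), Time × Treatment ANOVA with Tukey post-hoc
contrasts and automatic log/sqrt normality transforms, peak-to-trough
amplitude ratios, and phase-cluster summaries of differentially
expressed clock-controlled genes.

**Synthetic data** (`zeitgeber.simulate`). Generators for all three
input kinds with known ground truth: rhythmic (possibly bimodal)
replicate tables with multiplicative lognormal noise, damped drifting
reporter traces, and von Mises phase samples. Deterministic under a
seed.

## Worked example

```python
import numpy as np
from zeitgeber import (ExperimentDesign, RhythmParams, simulate_timecourse,
                       TimePointSeries, fit_cosinor, amplitude_ratio)

design = ExperimentDesign(n_per_cell=5, seed=42)          # ZT0,4,...,20
params = {
    ("per2", "control"): RhythmParams(mesor=3.0, harmonics=((1, 1.8, 10.2),), noise_cv=0.2),
    ("per2", "alcohol"): RhythmParams(mesor=4.2, harmonics=((1, 1.1, 6.5),), noise_cv=0.2),
}
table = simulate_timecourse(design, params)

for treatment in design.treatments:
    fit = fit_cosinor(TimePointSeries.from_timecourse(table, "per2", treatment))
    print(f"{treatment:8s} H={fit.n_harmonics} mesor={fit.mesor:.2f} "
          f"amp1={fit.amplitude(1):.2f} CG=ZT{fit.cg:.1f} p={fit.p_value:.2e}")

ctrl = TimePointSeries.from_timecourse(table, "per2", "control")
alc  = TimePointSeries.from_timecourse(table, "per2", "alcohol")
ar = amplitude_ratio(ctrl, alc)
print(f"peak-to-trough: control {ar.control_p2t:.1f}, alcohol {ar.alcohol_p2t:.1f}, "
      f"ratio {ar.ratio}")
```

prints

```
control  H=2 mesor=3.07 amp1=1.95 CG=ZT10.1 p=4.15e-14
alcohol  H=1 mesor=4.36 amp1=1.18 CG=ZT6.5 p=3.61e-06
peak-to-trough: control 3.8, alcohol 1.7, ratio 0.5
```

The control profile is rhythmic with its center of gravity at ZT10.1,
close to the simulated acrophase of 10.2 (an extra harmonic was picked
up from replicate noise, which barely moves the CG); the alcohol profile
is recovered with its advanced phase (ZT6.5) and elevated baseline. The
amplitude ratio of 0.5 means the alcohol profile's peak-to-trough fold
change is half the control's.

A full demo pipeline — simulation through rhythm detection,
phase-distribution tests and amplitude ratios, with all CSV outputs, a
log and a JSON report — runs from the shell:

```
zeitgeber run --seed 1 --out demo_run
```

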