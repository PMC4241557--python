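# Methods

This note documents the models, conventions and design choices behind
`ephysdev`: what the synthetic-data generator emulates, how each of the 16
electrophysiological parameters is measured, how the statistical and
multivariate stages are specified, and what the package's tests do and do
not establish about real recordings.

Canonical units throughout: mV, pA, ms (MΩ, pF for passive properties;
seconds for interspike intervals, percent for their coefficient of
variation).  The default sampling step is 0.05 ms (20 kHz); AP metrics
require ≤ 0.1 ms.

## The synthetic cohort

No raw recordings are available for the developmental study this package
operationalizes, so the pipeline is exercised on synthetic neurons whose
per-stage parameter distributions are calibrated to the published
descriptive statistics (mean, SD, N of 16 parameters over the 15 postnatal
stage bins P2–P3 … P28–P29; transcription in
`src/ephysdev/data/table1_calibration.csv`).  The generator's job is not to
be a biophysical model — there is no Hodgkin–Huxley machinery anywhere —
but to produce traces from which the extractor must recover known ground
truth, and cohorts with the statistical structure the population analyses
assume.

**Parameter sampling.** Each neuron's parameters are drawn from truncated
normals around its stage's calibrated mean/SD.  Two conventions matter:

* *Mean-preserving truncation.* Truncation intervals are symmetrized about
  the mean (half-width = min(mean − lo, hi − mean, 4 SD)), so sample means
  are unbiased estimators of the calibration means; the cost is a slightly
  shrunken SD whenever a legal bound lies within ~2 SD of the mean (e.g.
  CV_ISI at the late stages).  Legal bounds are the physical/invariant
  ranges (positive resistances, negative decay slopes, …); the rise slope
  is additionally bounded below at 12 mV/ms so every rendered AP stays
  visible to the 10 mV/ms spike-detection criterion (published rise slopes
  never approach that bound).
* *Latent maturation factor.* Within a stage, one standard-normal factor
  per neuron loads (ρ = 0.6) on every parameter with a clear developmental
  trend, oriented by the calibration's own early-vs-late direction.  A
  neuron that is more mature than its stage-mates in one property is
  therefore more mature in the others, reproducing the coherent
  within-stage blocks that real developmental cohorts show, while leaving
  every marginal mean and SD exactly as calibrated.  Without this coupling
  the three firing-regime classes are not recoverable by clustering at any
  realistic sample size.

The default cohort plan apportions 263 neurons over the 15 stages by
largest remainder, weighted by the per-stage minimum N across the 8
spontaneous-activity parameters (the neurons for which the multivariate
table is complete).  The published per-parameter Ns are mutually
inconsistent (the CV_ISI column alone sums to 271), so some such convention
is unavoidable; it is configurable via the stage plan.

**Spike trains.** Regular and irregular regimes are gamma-renewal
processes: shape k = 1/CV², scale = mean·CV², giving closed-form CV control
(CV = 1/√k; CV = 0 degenerates to a periodic train).  Bursting is an
alternating burst/pause renewal process: n spikes at a fixed intra-burst
interval i, then a pause with mean p = n·m − (n−1)·i (so the composite mean
ISI is m) and optional gamma jitter.  The composite CV² is
((n−1)d² + σ²/n)/m² with d = m − i; the solver picks the largest n whose
deterministic CV does not overshoot the target (intra-burst interval preset
80 ms, lengthened when even two-spike bursts overshoot) and adds pause
jitter σ to make up the remainder.  Spikes closer than the AP-template
support are thinned at render time (a refractory constraint); the
ground-truth ISI statistics of record are those of the spike train actually
rendered.

**AP template.** The action potential is an analytic piecewise waveform
constructed so that every extracted metric has a closed-form target:

1. a fast foot (half-cosine, peak velocity ≤ 7 mV/ms) from baseline to
   within a few mV of threshold;
2. a slow approach (8 ms half-cosine) whose velocity stays below 5 % of
   the rise's peak dV/dt, so the threshold criterion lands at the
   `threshold` parameter;
3. a half-cosine rise of duration 1.3552·A/rise_slope, whose 10–90 %
   time-averaged slope equals `rise_slope` exactly;
4. a short plateau carrying a 0.03 mV dome (unambiguous peak sample even
   on a drifting baseline); its duration absorbs the half-width degree of
   freedom;
5. a three-segment piecewise-linear decay (peak→90 %, 90→50 %, 50→10 % of
   amplitude above threshold) solved so that the half-width and the mean
   10–90 % decay slope both hit their targets — half-widths below
   T_rise/2 + 0.1·t_band are geometrically unrealizable and are clipped up
   at sampling time (the clipped value is the ground truth of record);
6. a linear descent into a quadratically eased trough at
   threshold − ahp_depth, then a half-cosine relaxation to baseline.

Segments are laid out in continuous time and sampled once, so no
per-segment rounding accumulates.  The interspike baseline is tied to the
AHP trough (baseline = threshold − ahp_depth + min(3, ahp_depth/2)),
mirroring the fact that in a pacemaking neuron the AHP trough *is* the
voltage minimum.

**Protocols.** Passive responses are ideal RC charging curves
(ΔV = I·R_in, τ = R_in·C_m; pulses auto-scaled to −5 mV, and the generator
refuses deflections ≥ 10 mV, mirroring the passive-fit inclusion rule).
The sag response is a double exponential — fast RC hyperpolarization
overshooting a trough plus a slower depolarizing relaxation (sag_tau,
floored at 2·τ_m so a trough exists) — whose two amplitudes are solved
numerically so the trace ends at −85 mV and the *measured* sag equals the
requested amplitude exactly; a rebound AP is pasted at the requested delay
on a slow ramp that lifts the recovering trajectory onto the template
baseline.  f–I responses place spikes so that the first two and last two
interspike intervals equal the periods implied by GS·I/100 and GE·I/100
exactly, with a geometric bridge emulating adaptation; pulse amplitudes
are auto-ranged per neuron (slow, low-gain cells need stronger currents
before a 1 s pulse holds enough APs for the regression) and pulses above
the saturation current cease firing 400 ms in, emulating depolarization
block.

## Feature extraction

* **Spike detection** (the acquisition criterion is a package convention,
  configurable): coarse derivative (symmetric difference over ±0.25 ms,
  robust to 0.3 mV recording noise) exceeding 10 mV/ms opens an event; the
  event time is the voltage maximum before the derivative turns negative;
  events peaking below −20 mV are rejected; 2 ms refractory.
* **ISI statistics** need ≥ 3 spikes spanning ≥ 40 s (the stable-recording
  inclusion rule); CV uses the sample (n−1) SD.
* **AP averaging**: peak-aligned windows (−10/+60 ms), truncated windows
  excluded; a second pass re-aligns each window on the first-pass average
  by minimizing the sum of squared differences over ±0.25 ms, because
  noise-induced jitter of the per-spike peak sample would otherwise smear
  the averaged rise.  The average can sit a sample off the ideal template;
  all downstream metrics are shift-invariant.
* **Threshold**: the voltage where dV/dt first reaches 5 % of its peak,
  found by walking backward from the dV/dt peak with linear interpolation.
* **Amplitude** is threshold→peak (the AHP shares the threshold reference);
  half-width is measured at threshold + amplitude/2; the 10–90 % slopes
  are ΔV over the time between the linearly interpolated 10 %/90 % level
  crossings, i.e. the time average of dV/dt over the band (equivalent to a
  per-sample mean but free of band-edge discretization error); AHP =
  threshold − post-peak minimum, clipped at 0 from below.
* **Passive fit**: least-squares mono-exponential over the pulse epoch
  (window read from the current command); R_in = |ΔV/I|, C_m = τ/R_in — so
  τ_m = R_in·C_m holds by construction, never by a second fit.
* **Sag**: mean over the last 50 ms of the pulse minus the pulse minimum
  (minimum taken on a 1 ms boxcar-smoothed copy; the raw extreme of 2·10⁴
  noisy samples would bias the sag up by ~3.5 σ).  Rebound delay runs from
  pulse offset to the first detected spike *peak* (the onset/peak ambiguity
  is resolved toward the peak).
* **Gains**: per pulse, f_start = mean instantaneous frequency of the
  first three APs (two leading ISIs) and f_end of the last three; a pulse
  is saturating when its spike count drops below the preceding pulse's or
  when firing ceases before the end (no spike in the final
  max(200 ms, 2.5 median ISIs) — the median-scaled term keeps slow
  sub-4-Hz pulses from being misread as depolarization block).  GS and GE
  are 100× the OLS slopes of f vs I over the maximal leading
  non-saturating run (≥ 3 pulses with ≥ 4 spikes); SFA = GS/GE.  Note that
  SFA computed from cohort-mean gains differs from the mean of per-neuron
  SFA values; the package always reports the per-neuron ratio.

The generator/extractor round-trip contract (noiseless, 20 kHz, 500 s
spontaneous traces): AP metrics within 2 % (or 0.5 mV / 0.05 ms), passive
parameters within 1 %, ISI statistics within 5 % of the rendered train's
realized statistics, gains within 10 %.  The realized train is the
reference for ISI metrics because renewal sampling noise at CV ≈ 130 %
over 500 s is itself ~5 % — the contract certifies extraction fidelity,
not renewal convergence, which is tested separately.

## Statistics

Each parameter is analyzed independently: one-way fixed-effects ANOVA over
the stage groups with protected post-hoc Tukey HSD (Tukey–Kramer for the
unbalanced groups; pairwise codes are only assigned when the omnibus test
is significant at 0.05, the classical protected convention — it also gives
the procedure a familywise false-positive rate strictly below 5 % per
parameter, which the calibration test verifies on all-null cohorts).
Codes use strict binning: ns, p < 0.05, p < 0.01, p < 0.001; parameters
without data in a stage are coded `nm` (not measured), distinct from ns.
Compound stage bins (P8–P9, …) are single groups.  No correction is
applied across the 16 parameters — they are reported as independent
univariate analyses.  Degenerate inputs (all values identical) yield p = 1
rather than an error.

## Multivariate analysis

Only the 8 spontaneous-activity parameters enter (ISI_avg, CV_ISI, AP
threshold, amplitude, rise slope, decay slope, half-width, AHP), in that
fixed column order: the point of the analysis is that phenotype is
definable without current injection.  Rows with any missing value among
the 8 are rejected, never imputed.

* **Normalization**: each column is divided by |population mean| (sign
  preserved for the negative-mean threshold column), applied before *both*
  clustering and PCA; `zscore` and `none` are available as configuration.
  Under mean normalization CV_ISI, whose population mean is small relative
  to its developmental range, dominates the metric — this is what makes
  the bursting class separable, and z-scoring (tested) merges it into the
  young class.
* **Clustering**: Ward linkage on Euclidean dissimilarities
  (scipy's Lance–Williams implementation; the test suite holds it to an
  exhaustive-search oracle for n ≤ 6).  The automatic cut sits in the
  largest gap between consecutive merge heights among the top
  min(n−1, 10) merges; a fixed class count `k` can override it.  Per
  class: centroid (normalized units), central object (member nearest the
  centroid, ties to the lowest row index) and mean ± SD age.
* **Cluster-count caveat.**  On the full 15-stage cohort the stage bins
  form a near-continuum and the bursting class is small (~15 of 263
  neurons), so the 2-vs-3-class decision is genuinely ambiguous: the
  largest-gap rule (and every standard index tried — relative gap,
  Calinski–Harabasz, silhouette, Davies–Bouldin, gap statistic,
  inconsistency) oscillates between 2 and 3 across seeds.  Cut at k = 3,
  the classes are the bursting/irregular/regular triad with mean ages
  ≈ P3/P7.5/P18.  The structural acceptance test therefore exercises the
  automatic cut on a scaled-down cohort of the three canonical stages
  (P2–P3, P7, P21–P23; 30 neurons each), where the three classes separate
  robustly; the full-cohort automatic k is reported, not asserted.
* **PCA**: eigendecomposition of the divisor-n (population) covariance of
  the normalized table (the divisor only scales eigenvalues; a switch
  selects n−1).  Sign convention: each component's largest-magnitude entry
  is positive.  Scores ("factor loadings" F1, F2) are the centered data
  projected on the components; supplementary observations (perturbed
  cohorts) are normalized with the *training* divisors, centered with the
  training means and projected without refitting.
* **Trajectory and variability**: per-stage mean/SD/SEM of (F1, F2)
  ordered by age; variability ellipses A = π·SD(F1)·SD(F2); Pearson
  correlation of SD(F1) against stage mean age, reported signed with its
  two-sided t-based p.

## Perturbation emulation

Pharmacology acts at the generator-parameter level: an AHP block fraction
f scales ahp_depth by (1 − f) and raises the spike-train CV through an
explicit monotone coupling CV′ = CV·(1 + κ·f) (κ default 4; the coupling
between SK-current block and firing irregularity is real but unquantified,
so κ is an explicit construct, not a fitted constant).  Low-dose TTX
scales AP amplitude and both slopes by `sodium_scale` (default 0.8, a
placeholder configuration value).  The dynamic-clamp leak is exact
conductance arithmetic: g = 1000/R_target − 1000/R_in (nS, MΩ), reversal
−65 mV, default target 1600 MΩ (the neonatal input resistance); the leak
changes only the apparent R_in, never the AP shape parameters, matching
the observation that leak subtraction alone does not move the
spontaneous-activity phenotype.  Shift vectors are differences of mean
supplementary scores of paired before/after cohorts, optionally translated
onto class-centroid anchors for display.

## Problem sizes and numerical choices

Defaults: 20 kHz sampling, 60 s spontaneous traces (500 s in the
round-trip acceptance test, where ISI statistics are held to 5 %),
0.3 mV Gaussian recording noise, two passive pulses, one sag pulse and six
auto-ranged f–I pulses per neuron.  Cohorts stream neuron by neuron
through generation and extraction (one rendered neuron is ~20 MB).  All
level crossings are linearly interpolated; random draws go through
`numpy.random.Generator` seeded from a single integer, and identical
(config, seed) reproduce outputs byte-identically.

## What passing tests do and do not show

The synthetic cohort reproduces the calibrated stage means/SDs, the three
firing regimes, and coherent within-stage covariation — but its
correlation structure is a one-factor construction, its AP is an analytic
template (no channel noise, no electrode artifacts, no junction-potential
or bridge-balance errors), and its bursting statistics are presets (the
study does not quantify intra-burst structure).  Passing round trips
certify that the extractor measures what the definitions say on clean,
well-behaved waveforms and that the statistical/multivariate machinery is
correctly specified; they do not certify detector robustness against
recording artifacts absent from the generator, and quantities such as the
PC1+PC2 variance share are expected to differ from values measured on real
neurons (whose parameter covariance is richer than one latent factor).
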