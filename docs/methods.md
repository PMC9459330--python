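# Methods

`patchfeat` analyses whole-cell patch-clamp recordings from current-step,
burst (AHP) and continuous voltage-clamp protocols, and validates every
measurement by parameter recovery on simulated traces with exact ground
truth. This note documents the models, the measurement definitions, the
numerical choices, what the simulator does and does not emulate, and the
known limitations of the statistical layer.

## Measurement definitions

**Units.** mV, pA, MΩ, seconds throughout; conversions happen only at I/O.

**Input resistance (R_in).** Steady-state membrane voltage is measured on
each of the seven −100…+50 pA steps (25 pA increments from a −70 mV
baseline) as the mean over the last 100 ms of the step; R_in is the
ordinary-least-squares slope of the V–I relation, converted to MΩ. Sweeps
containing spikes inside the step are excluded from the fit (the +50 pA
step can be suprathreshold in high-resistance cells); steady-state rather
than peak voltage is used for hyperpolarizing steps, keeping the sag
analysis separate.

**Spike detection and rheobase.** Spikes are suprathreshold peaks
(> 0 mV, ≥ 1 ms apart). Rheobase is the smallest step current with at least
one spike on the 25 pA grid; a cell with no spikes up to +375 pA is reported
as NaN and excluded from group averages.

**AP threshold.** First derivative of the first spike at rheobase; the
threshold is the membrane potential at the last sample before the peak
where dV/dt has fallen to 5% of its maximum, searching backward from the
maximum-dV/dt point within the 10 ms preceding the peak. Ties at exactly 5%
take the earliest sample. Because the criterion is relative, it is
invariant to voltage scaling about the threshold.

**AP height and width.** Height is threshold-to-peak. FWHM is the time
between the two crossings of threshold + height/2, linearly interpolated
between samples.

**Sag and rebound.** For each of the four hyperpolarizing steps
(−100…−25 pA): V_h is the mean over 100 ms pre-onset, V_SS over the last
100 ms of the step, V_SAG is the extremum within the first 200 ms of the
step minus V_SS, and V_rebound the post-offset maximum within 200 ms minus
V_h. The sag ratio is (V_SAG + (V_SS − V_h)) / (V_SS − V_h), averaged over
the four steps per cell; steps with |V_SS − V_h| < 0.5 mV are skipped to
avoid a near-zero denominator. The rebound analysis pools one
(V_SS, V_rebound) point per cell × step and compares group regression
slopes by ANCOVA.

**AHP.** The burst protocol holds −60 mV and injects 4 × 2 nA / 2 ms pulses
at 70 ms start-to-start spacing within a 2 s sweep. The medium AHP is the
minimum of (V − V_hold) between the last pulse offset + 10 ms (blanking the
pulse/spike artifact) and 500 ms; the slow AHP is the signed trapezoidal
area of (V − V_hold) over 500–2000 ms, so depolarizing excursions subtract.
The mAHP window is a package choice — only the 500–2000 ms AUC window is
prescribed by the analysis being reproduced.

**PSC events.** A fixed 9 pA amplitude threshold on 300 s voltage-clamp
traces at −70 mV. Baseline is a 50 ms running median; candidates are local
minima of the baseline-subtracted current deeper than the threshold, ≥ 5 ms
apart (larger event kept); amplitude is refined as a 5 ms pre-event mean
(ending 3 ms before the trough) minus the trough, and must itself reach the
threshold. The threshold applies to baseline-subtracted current, making
detection invariant to holding-current offset. Instantaneous frequency is
1/inter-event-interval; per-cell means feed the group tests and pooled
per-event values feed cumulative comparisons. Detection is fully automated;
no manual confirmation step is modelled, and no kinetics-based filtering is
applied.

**QC gate.** Cells enter the excitability analysis only with |leak| <
100 pA at the −70 mV hold and access resistance < 25 MΩ (strict); the PSC
arm uses Ra ≤ 25 MΩ and Ra drift < 20% during collection. Each failed
criterion contributes exactly one reason, so the gate is monotone: worsening
a criterion can only add reasons. Ra is consumed as supplied metadata, not
estimated from sweeps. The ~12 mV liquid-junction offset of gluconate-based
internals is deliberately *not* corrected, matching the recordings emulated.

**Plaque quantification.** Images are linearly rescaled to 8-bit; percent
area is the exact count of ROI pixels strictly above one global threshold
(configurable to ≥), divided by ROI pixel count. The threshold is a
required input — it must be determined once and maintained across images.

## The simulator

Waveforms are phenomenological, assembled from analytic kernels so that
ground truth is exact by construction rather than emergent from
conductance dynamics:

- Passive steps charge exponentially (τ_m, default 22 ms) to exactly
  I·R_in; sag is a normalized rise to exactly sag_ratio × ΔV_SS followed by
  exponential relaxation to ΔV_SS; the rebound rises to exactly
  intercept + slope·V_SS above baseline before decaying.
- Spikes are pasted templates with half-cosine rise and fall whose
  durations sum to 2 × FWHM, so threshold, peak and width are exact; the
  template starts at threshold with zero slope, keeping subthreshold dV/dt
  far below 5% of the template's maximum so the threshold rule recovers the
  programmed value. Firing follows f = gain·(I − I_θ) with the first spike
  at the passive threshold crossing and ISIs lengthened by
  (1 + adaptation·k). This couples rheobase and the F–I curve to R_in, as
  in real membranes: rheobase ≈ (V_th − V_h)/R_in on the 25 pA grid.
- The AHP sweep superposes two raised-cosine components: a trough centred
  at 350 ms whose minimum is exactly the programmed mAHP (the centre falls
  on a sample), and a slow bump supported inside 0.5–2.0 s normalized so its
  analytic integral equals the programmed AUC.
- PSC events are inward bi-exponential kernels (τ_rise 0.5 ms, τ_decay
  5 ms) with unit-normalized peaks at Poisson or regular times on Gaussian
  noise; well-separated mode thins Poisson times to ≥ 3·τ_decay spacing.
  Ground-truth event tables are returned alongside each trace.
- Plaque images place exactly round(fraction × ROI pixels) suprathreshold
  pixels inside the ROI, with bright clutter outside it.

Sampling is 20 kHz by default (the emulated acquisition rate), and every
generator is deterministic per seed. Cohorts draw per-cell parameters from
per-genotype normal distributions whose means are the reported group means
of the study emulated and whose SDs are reconstructed as SEM·√n (n ≈ 35
cells/group for current-clamp features, 32 for PSC), with physical floors
(e.g. sag ratio ≥ 1, PSC rate > 0.2 Hz). Full cells are tens of MB;
`iter_cohort` streams them so `run_study` can analyse large cohorts in a
single pass at ~0.3 GB peak memory.

What the simulator does **not** emulate: conductance-based spike dynamics,
channel noise, electrode/access-resistance artifacts, seal instability,
temperature effects, or correlated (non-Gaussian) recording noise. Passing
recovery tests therefore demonstrates the *measurement* code is correct and
unbiased on idealized data — not that the pipeline is robust to every
pathology of real recordings.

## Statistics

Per-feature two-group comparisons are gated: Shapiro–Wilk on each group at
α = 0.05 plus Levene's test for equal variances (the normality wording of
the recipe mentions equal variances without naming a test; Levene is used
and can be disabled); both pass → unpaired Student's t, otherwise two-sided
Mann–Whitney U. The gate that fired is recorded on each result. PSC
per-cell means use Mann–Whitney directly, as prescribed. The F–I table is
analysed by a mixed-design ANOVA (between: genotype, within: current step,
subject: cell) via pingouin; cells missing any step are dropped, and the
reported degrees of freedom follow this design rather than any particular
published table. Rebound slopes are compared by the interaction F-test of
V_rebound ~ V_SS × group (statsmodels OLS/ANCOVA). Bonferroni adjustment
(min(1, p·k)) is available for post-hoc use but no correction is applied
across the feature family. Measured under Gaussian nulls (1000 reps), the
gated test's type-I error is 0.050 at n = 15/group; the KS test is 0.043 at
n = 500 and conservative (0.023) at n = 15 because of its discrete exact
small-sample distribution.

Two caveats of the emulated analysis carry over and are worth knowing:

1. **Pooled-event KS is pseudo-replicated.** Pooling thousands of events
   that cluster within tens of cells violates independence; with realistic
   between-cell heterogeneity the pooled KS rejects far above the nominal
   rate even when group distributions are identical. The per-cell
   Mann–Whitney comparisons are the reliable ones.
2. **Noise biases extremum-based measures.** Sag, rebound and mAHP take the
   minimum/maximum of a noisy trace, which inflates them by an amount that
   grows with noise and shrinks with deflection size. The bias is shared
   between groups, so comparisons remain valid, but absolute values from
   noisy data exceed the noise-free ground truth. Similarly, the PSC
   detector's trough-picking inflates amplitudes under noise.

## Numerical choices and degenerate inputs

Sampling must be uniform within 1 ns; OLS fits use closed-form polynomial
least squares; the AUC uses trapezoidal quadrature (agrees with a
10×-resolution Riemann sum to < 1e-3 mV·s); FWHM crossings are linearly
interpolated; the running-median baseline is computed on a 1 kHz decimated
copy of the trace and interpolated back (indistinguishable from the
full-rate median for ≥ 5 ms kernels, and linear-time on 6 M-sample traces).
Division-hazard cases are explicit errors or skips: sag steps with < 0.5 mV
deflection, V–I fits with < 2 usable points, AHP sweeps shorter than 2 s,
cells with < 3 values per group in any test. An exactly collinear ANCOVA
(zero residual variance, identical groups) reports F = 0, p = 1 rather
than NaN.

## Problem sizes used in the test suite

Recovery tests run noise-free single cells at 20 kHz; the type-I suites use
1000 replicates; the whole-pipeline checks use 5 seeded cohorts of 40
cells/group (null) and 100 cells/group (effect direction, chosen by a
priori power analysis for ~0.9 power at the reported effect sizes) with
12 s PSC traces per cell. These sizes are the package's own choice of a
thorough-but-quick default; all generators accept larger values.
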