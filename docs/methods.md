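# Methods

## Scope and intent

`tdmassay` couples two things that are usually done separately: deciding what
concentration range a therapeutic-drug-monitoring assay must cover (a
population-pharmacokinetic question) and demonstrating that a candidate assay
covers it acceptably (a bioanalytical-validation question). Because no
instrument is attached, a synthetic-data generator stands in for the HPLC
fluorescence detector; its purpose is to reproduce the *statistical* structure
validation statistics respond to, not the chemistry of any particular column.

## Pharmacokinetic range simulation

The disposition model is a one-compartment body with first-order elimination,
k = CL/V. Intravenous dosing is a zero-order infusion over T_inf; oral dosing
is first-order absorption with rate ka and bioavailable fraction F. Both
single-dose solutions are closed forms; repeated dosing is exact superposition
of time-shifted single doses (linear PK), so no steady-state shortcut is used
and partial accumulation during the first week is represented exactly. When
|ka − k| < 1e-8·k the Bateman equation degenerates numerically and the
L'Hôpital limit F·D·k·t·e^(−kt)/V is substituted.

Interindividual variability is sampled per parameter from independent
log-normal distributions. Reported PK summaries are conventionally arithmetic
mean ± SD, so the log-normal is moment-matched (μ = ln(m²/√(m²+s²)),
σ² = ln(1 + s²/m²)); a `log_scale` switch instead interprets the inputs as
median and log-SD. No covariance between parameters is imposed — none is
available to inform one. Bioavailability draws are truncated at 1.0 to keep F
physical; with realistic F CVs (<10%) the truncated mass is negligible.

Defaults: 200 mg every 24 h for 7 doses (1-h infusion for the iv route),
1000 subjects, a 0.1-h time grid, and an example adult parameter set
(CL 6.9 ± 1.5 L/h, V 80 ± 16 L, ka 1.2 ± 0.5 h⁻¹, F 0.86 ± 0.08). The
parameter set is deliberately configuration, not a built-in truth: assay
designers should substitute the population appropriate to their drug.

The envelope is the empirical 2.5th/97.5th percentile per time point
(numpy linear interpolation between closest order statistics), evaluated at
the day-1 and day-7 pre-dose troughs (t = 24 h and t = 168 h exactly; a dose
administered at the evaluation instant contributes nothing at that instant).
The range rule is conservative across all route/day combinations supplied:
the admissible LLOQ is half the *smallest* lower percentile and the
admissible top calibrator twice the *largest* upper percentile.

## Synthetic instrument

A chromatogram is a uniform time grid (15 min at 120 points/min) carrying a
constant baseline, additive white Gaussian noise (SD 0.15 fluorescence units),
and symmetric Gaussian peaks: the analyte near 12.9 min and the IS near
8.8 min, both with σ = 0.05 min and retention jitter of SD 0.007 min.
Symmetric peaks reflect a well-behaved isocratic separation; tailing is
deliberately not modelled (a config hook exists for an exponential-tail
convolution should it ever matter to a statistic).

Peak height is proportional to concentration (100 height units per µg/mL by
default; the IS is a fixed-amount spike at 1000 units) with a mean-one
log-normal replicate-to-replicate error of CV 0.5%, drawn independently for
analyte and IS so the height *ratio* carries compounded noise (≈0.7%). An
extraction-efficiency factor (default 1.0) separates protein-precipitated
samples from pre-spiked reference standards for the recovery comparison, and
an optional between-day response multiplier (default off) makes intra- and
inter-assay scatter distinguishable on demand.

This architecture — small proportional error plus additive baseline noise —
reproduces the characteristic precision profile of height-ratio assays: ~0.5%
RSD at the high QC where proportional error dominates, rising toward ~15-20%
at the LLOQ where baseline noise and calibration-intercept uncertainty
dominate. What the generator does *not* emulate: matrix-effect chemistry,
carryover, column aging, drift within a run, or non-Gaussian noise. Passing
validation on synthetic data therefore demonstrates that the *statistical
pipeline* is correct and that the assumed noise magnitudes pass the gates;
it cannot certify a physical instrument.

Sample-preparation arithmetic is kept explicit so nominal concentrations trace
to a plan: a stock of mass/volume (1 mg in 4 mL → 250 µg/mL) is serially
diluted and spiked 20 µL into 80 µL serum, so working solutions are 5× the
final serum concentration. Calibrators span 0.025–10.0 µg/mL at seven levels;
a 0.01 µg/mL preparation exists purely as a detection-limit probe and is never
fitted. QC levels are 0.025 (LLOQ), 0.1 (low), 5.0 (medium) and 10.0 (high)
µg/mL, three replicates per day for three days.

## Peak processing

The baseline level is the median, and the baseline noise the sample SD, of a
signal-free window (1.0–5.0 min by default, ≥20 points, forbidden to overlap
a peak window). Peaks are the highest local maximum inside a ±0.2-min
retention window whose baseline-corrected height exceeds 3× the noise SD;
exact ties resolve toward the expected retention time, then earlier. Height,
not area, quantifies (area is computed and reported). S/N is height over the
baseline-noise SD — the SD convention is stable on synthetic data and is the
common pharmacopoeial-adjacent choice; the true instrumental procedure behind
any published S/N is rarely stated, so the definition is configurable in
spirit (a peak-to-peak/5 variant would slot into `signal_to_noise`).

LLOD is the lowest level whose worst-run S/N exceeds 3; LLOQ the lowest with
worst-run S/N above 10 *and* intra accuracy within 80–120% and precision
below 20% at that level. Undetermined limits are values (None), not errors.

## Calibration and validation statistics

The calibration line is fitted by statsmodels WLS; the default is unweighted,
matching the plain linear-regression convention, with 1/x and 1/x² weights
exposed because a 400-fold dynamic range makes them defensible. R² is the
squared correlation of fitted vs observed (the WLS analogue under weighting).
The intercept is estimated, not forced through zero. Back-calculation is the
algebraic inverse; sub-blank ratios yield negative concentrations returned
as-is for the caller to flag.

Accuracy uses the scope's mean back-calculated concentration; precision is
the sample RSD (n−1 denominator throughout). Intra-assay statistics summarise
within-day replicates (n = replicates; the report pools days by averaging the
per-day means and RSDs), inter-assay statistics are computed over the per-day
means (n = days). Acceptance is a closed accuracy interval and a strict
precision inequality; the LLOQ level uses the relaxed limits.

A consequence worth knowing: with an unweighted fit, the curve's intercept
uncertainty (driven by absolute residuals at the top calibrators) propagates
roughly 0.004 µg/mL into every back-calculated value, which is ~16% of a
0.025 µg/mL LLOQ. Inter-assay LLOQ precision is therefore *borderline by
construction* (~15–20%), and seeds exist on which the default configuration
fails the <20% LLOQ gate or promotes the LLOQ to the next level. This mirrors
how such assays behave in practice at n = 3 and is the strongest argument for
the 1/x² weighting option. Integration tests pin seeds; the acceptance-gate
logic itself is deterministic.

Recovery is the ratio of mean extracted-sample height to mean reference
height per level and day (analyte and IS separately); selectivity screens
blank injections for any detected peak reaching 20% of the LLOQ analyte
response or 5% of the IS response in the respective windows, with ties
failing.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed (numpy `default_rng`);
identical seeds give byte-identical CSV outputs. The shipped studies use
1000 simulated subjects for the range stage, 3 days × 3 replicates for the
validation campaign, 500 seeded runs for the calibration-linearity study and
200 seeded one-day campaigns for the parameter-recovery study — sizes at
which the sampling distributions of the reported statistics are already
narrow while a full run stays interactive on a laptop.

## Known limitations

- One-compartment linear PK only; no covariate or multi-compartment models,
  and no estimation from observed concentrations.
- Independent log-normal parameters; real CL–V correlation would narrow the
  simulated envelope somewhat, making the derived range conservative.
- The generator's error model is stationary within a run; drift and
  autocorrelated noise are absent, so baseline estimation is easier than on
  real traces.
- Stability, matrix-effect, dilution-integrity and carryover validation arms
  are out of scope.
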