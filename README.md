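# tdmassay

Design and validate a serum drug-concentration assay before (or alongside) the
instrument work: `tdmassay` simulates the patient concentrations a therapeutic
drug monitoring (TDM) assay must cover, generates synthetic HPLC-fluorescence
chromatograms with realistic noise, and runs the complete FDA-style
bioanalytical validation — calibration, accuracy, precision, LLOQ/LLOD by
signal-to-noise, recovery and selectivity — with pass/fail gating.

The worked defaults model a serum assay for tedizolid, an oxazolidinone
anti-MRSA antibiotic quantified against an internal standard (IS) over a
15-minute isocratic run, but every quantity is configuration.

## The models

**Range design.** Patient concentrations are simulated under a one-compartment
model with elimination rate k = CL/V. For a zero-order infusion of duration
T<sub>inf</sub> (rate R₀ = D/T<sub>inf</sub>):

    C(t) = R₀/CL · (1 − e^(−kt))                         t ≤ T_inf
    C(t) = R₀/CL · (1 − e^(−kT_inf)) · e^(−k(t−T_inf))   t > T_inf

and for first-order oral absorption (Bateman):

    C(t) = F·D·ka / (V·(ka−k)) · (e^(−kt) − e^(−ka·t))

Multiple dosing is exact superposition of time-shifted single doses.
Interindividual variability is drawn log-normally, moment-matched to the
configured arithmetic mean/SD of CL, V, ka, F. From n = 1000 simulated
subjects the 2.5th/97.5th percentile envelope at the day-1 and day-7 troughs
fixes the admissible calibration range: **LLOQ < ½ × (smallest lower
percentile)** and **top calibrator > 2 × (largest upper percentile)**.

**Validation.** The response is the analyte/IS peak-height ratio, fitted as
ratio = a·C + b by (optionally weighted) least squares across seven calibrators
spanning 0.025–10.0 µg/mL. QC samples are back-calculated through the curve and
judged by

    accuracy (%)  = C_measured / C_theoretical × 100
    precision (%) = SD / mean × 100

with acceptance limits 85–115% accuracy and <15% precision (80–120% / <20% at
the LLOQ). The LLOD is the lowest level with S/N > 3; the LLOQ additionally
needs S/N > 10 plus acceptable accuracy and precision. S/N is baseline-corrected
peak height over the SD of a signal-free baseline region.

## Worked example

```python
import tdmassay as t

cfg = t.RunConfig().validate()          # documented defaults
rng = t.run_range(cfg, seed=1)          # Monte-Carlo range design
print(rng.report(0.025, 10.0))

val = t.run_validation(cfg, seed=0)     # synthetic validation campaign
print(val.summary())
```

The range stage prints the simulated envelope and the derived rule:

```
 route  time_h    lower    upper
    iv      24    0.102    0.669
    iv     168    0.105    0.936
    po      24    0.076    0.604
    po     168    0.078    0.829

Admissible LLOQ     : < 0.03802 ug/mL (half the smallest lower percentile)
Admissible top cal. : > 1.873 ug/mL (twice the largest upper percentile)
Candidate range 0.025-10 ug/mL: satisfies the range rule
```

so a 0.025 µg/mL LLOQ and a 10.0 µg/mL top calibrator bracket the simulated
patient concentrations with margin. The validation stage then reports per-run
calibration parameters (slope ≈ 0.1 ratio per µg/mL, R² ≈ 1.0000), the QC
table — e.g. at the high QC an observed 10 ± 0.081 µg/mL, accuracy 100.1%,
precision 0.8%, pass — extraction recoveries near 100%, worst-run S/N per
level (17.0 at the 0.025 µg/mL LLOQ, 6.6 at the 0.01 µg/mL LLOD probe), and
the verdict:

```
LLOQ: 0.025 ug/mL | LLOD: 0.01 ug/mL
Selectivity: pass
Overall verdict: PASS
```

The same stages are available from the shell — `tdmassay range|synth|detect|
calibrate|validate|report|all`, each taking `--config` (YAML, see
`examples/tedizolid.yaml`), `--seed` and `--out`. Exit codes: 0 pass,
2 validation fail, 3 config error, 4 undetermined LLOQ.

## Layout

- `tdmassay.pk` — one-compartment simulation, percentile bands, range rule
- `tdmassay.synth` — synthetic chromatograms, dilution arithmetic, datasets
- `tdmassay.peaks` — baseline/noise estimation, peak detection, S/N, limits
- `tdmassay.calibration` — `CalibrationModel.fit()` → `CalibrationResults`
- `tdmassay.validation` — accuracy/precision/recovery/selectivity + gating
- `tdmassay.pipeline` / `tdmassay.cli` — orchestration and the console tool

See `docs/methods.md` for the model assumptions, noise architecture, numerical
choices and known limitations.
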