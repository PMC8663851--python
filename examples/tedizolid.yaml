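# Example run configuration: serum tedizolid assay design & validation.
# Every field is optional; omitted fields take the documented defaults.

pk:
  dose_mg: 200.0          # dose per administration
  interval_h: 24.0        # q24h regimen
  n_doses: 7              # 7-day horizon
  infusion_duration_h: 1.0
  routes: [iv, po]
  parameters:             # population means/SDs (example adult set)
    cl_mean: 6.9          # clearance, L/h
    cl_sd: 1.5
    v_mean: 80.0          # distribution volume, L
    v_sd: 16.0
    ka_mean: 1.2          # absorption rate, 1/h (oral only)
    ka_sd: 0.5
    f_mean: 0.86          # bioavailable fraction (oral only)
    f_sd: 0.08
  n_sim: 1000
  percentiles: [0.025, 0.975]
  eval_times_h: [24.0, 168.0]   # day-1 and day-7 pre-dose troughs
  time_step_h: 0.1

assay:
  geometry:
    run_time: 15.0        # min
    sampling_rate: 120.0  # points/min
    analyte_rt: 12.9      # min
    is_rt: 8.8            # min
    baseline_noise_sd: 0.15
  response:
    analyte_response_factor: 100.0   # height units per ug/mL
    is_response_height: 1000.0
    proportional_cv: 0.005           # replicate-to-replicate height CV
    rt_jitter_sd: 0.007              # min
  calibration_levels: [0.025, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0]
  llod_probe: 0.01        # prepared but never fitted
  qc_levels: [0.025, 0.1, 5.0, 10.0]
  lloq_candidate: 0.025
  top_calibrator: 10.0
  days: 3
  replicates_per_day: 3

analysis:
  weighting: none         # none | 1/x | 1/x2
  baseline_region: [1.0, 5.0]
  rt_tolerance_min: 0.2
  limits:
    accuracy_low: 85.0
    accuracy_high: 115.0
    precision_max: 15.0
    lloq_accuracy_low: 80.0
    lloq_accuracy_high: 120.0
    lloq_precision_max: 20.0

seed: 1234
outdir: tdmassay_out
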