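# Desk-scale preset: reduced cohort and optimizer budget for single-CPU runs.
name: desk-scale
scenario:
  n_participants: 1000
  n_trials_per_condition: 1000
  magnitudes: [0.3, 0.5, 0.7]
  scenarios: [amplitude, time_to_peak, both_conflict, nonconflict]
  task_types: [simon, flanker, stroop]
fitting:
  n_sim: 2000
  popsize: 8
  maxiter: 40
  tol: 0.001
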