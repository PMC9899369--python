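# Paper-scale preset: full cohort sizes (2,000 participants, 5,000 congruent
# and 5,000 incongruent trials each) and the full optimizer budget.
name: paper-scale
scenario:
  n_participants: 2000
  n_trials_per_condition: 5000
  magnitudes: [0.3, 0.5, 0.7]
  scenarios: [amplitude, time_to_peak, both_conflict, nonconflict]
  task_types: [simon, flanker, stroop]
fitting:
  n_sim: 10000
  popsize: 10
  maxiter: 200
  tol: 0.001
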