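# Oracle-objective run: exercises the full search loop in seconds without
# audio processing.  The objective has a known optimum, so the summary should
# report attack/release values close to the peak below.

audiogram:
  synthetic: {severity: moderate, seed: 7}

search:
  n_iterations: 1000
  n_threads: 4
  seeds: [1, 2, 3, 4]

scorer:
  kind: oracle
  peak_attack_ms: [140, 140, 140, 140, 140]
  peak_release_ms: [980, 980, 980, 980, 980]
  w_at: 10
  w_rt: 100

stimuli:
  synthetic: {n_items: 1, seed: 1}

output_dir: out/oracle
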