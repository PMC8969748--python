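# Smoke-scale end-to-end run: synthetic audiogram + synthetic stimuli +
# envelope-correlation proxy objective.  Completes in a few minutes on one CPU.
# Run from the repository root:  hafit run examples/smoke.yaml

audiogram:
  synthetic: {severity: moderately_severe, seed: 13}

ha:
  ig65_db: [10, 15, 20, 25, 25]
  ig85_db: [5, 8, 12, 15, 15]
  ct_db_spl: [45, 45, 45, 45, 45]
  limiter: {threshold_db_spl: 100, ratio: 10}
  default_tc:
    attack_ms: [200, 100, 100, 100, 100]
    release_ms: [2000, 1500, 1200, 1000, 1000]

search:
  n_iterations: 50          # production default is 1000
  n_threads: 4
  seeds: [101, 102, 103, 104]

scorer: {kind: proxy}

stimuli:
  synthetic: {n_items: 2, seed: 42, duration_s: 1.2, level_db_spl: 65}

output_dir: out/smoke
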