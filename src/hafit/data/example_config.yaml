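# hafit run configuration (YAML; JSON also accepted)

# Audiogram: one of csv / inline / synthetic
audiogram:
  synthetic: {severity: moderate, seed: 7}
  # csv: my_audiogram.csv                       # two columns with header
  # inline: {frequencies_khz: [...], thresholds_dbhl: [...]}

# Hearing-aid configuration. Gains and compression thresholds are inputs
# (e.g. from a prescription rule); they are never computed here.
ha:
  ig65_db: [10, 15, 20, 25, 25]        # per-channel insertion gain at 65 dB SPL input
  ig85_db: [5, 8, 12, 15, 15]          # ... at 85 dB SPL input (ig85 <= ig65)
  ct_db_spl: [45, 45, 45, 45, 45]      # compression thresholds (< 65 dB SPL)
  # channel_edges_khz: [0.1, 0.7, 1.4, 2.8, 5.6, 8.0]
  limiter: {threshold_db_spl: 100, ratio: 10, attack_ms: 5, release_ms: 50}
  # default_tc: time constants the search must beat; retained otherwise.
  default_tc:
    attack_ms: [200, 100, 100, 100, 100]
    release_ms: [2000, 1500, 1200, 1000, 1000]

# Hearing-loss simulator
hl:
  normal_dynamic_ceiling_db_spl: 100
  envelope_cutoff_hz: 32

# Contracting random search
search:
  at_bounds_ms: [10, 500]
  rt_bounds_ms: [300, 2000]
  stepsize_ms: 10
  n_iterations: 50          # smoke scale; production default is 1000
  n_threads: 4
  seeds: [101, 102, 103, 104]

# Objective: 'proxy' (envelope-correlation intelligibility proxy) or 'oracle'
scorer: {kind: proxy}

# Stimuli: synthetic speech surrogates or a directory of mono WAV files
stimuli:
  synthetic: {n_items: 2, seed: 42, duration_s: 1.2, level_db_spl: 65, sample_rate_hz: 22050}

output_dir: out
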