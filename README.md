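# hafit

Hearing-aid time-constant fitting by contracting random search.

`hafit` simulates the full evaluation chain used to tune per-channel attack
and release times of a multichannel wide-dynamic-range-compression (WDRC)
hearing aid for a given audiogram:

1. **Hearing-aid simulation** — a 5-channel simulator (band edges 0.1, 0.7,
   1.4, 2.8, 5.6, 8 kHz); each channel runs a WDRC compressor (static gain
   curve anchored at the 65- and 85-dB-SPL insertion gains, envelope follower
   with per-channel attack/release dynamics) followed by a fast limiter.
2. **Hearing-loss simulation** — loudness recruitment via multiband envelope
   expansion plus a linear-phase threshold-elevation filter, both driven by
   the audiogram.
3. **Objective scoring** — a pluggable `Scorer` interface. An external speech
   recognizer can be attached; the package ships an envelope-correlation
   intelligibility proxy (`ProxyScorer`) and a known-optimum synthetic
   objective (`OracleScorer`) for testing the search.
4. **Contracting random search** — per-channel attack (10–500 ms) and release
   (300–2000 ms) times are sampled on a 10-ms grid inside ranges centred on
   the incumbent; ranges shrink linearly each iteration down to twice the
   step size after N iterations. Several independent seeded threads run and
   the best result is kept; user-supplied default time constants are retained
   when nothing beats them.

Audiograms can be measured (CSV / inline), completed at missing audiometric
frequencies with a degree-3 least-squares fit in log-frequency, or generated
synthetically by severity class. All randomness flows from explicit seeds;
every run is bit-reproducible.

## CLI

```sh
hafit run examples/smoke.yaml        # full chain on synthetic stimuli (~1 min)
hafit run examples/oracle.yaml       # search only, known-optimum objective (seconds)
hafit synth-audiogram --severity moderate --seed 7 -o ag.csv
hafit init-config -o myrun.yaml      # documented starter config
hafit verify                         # quick search-invariant self-checks
hafit trace-plot out/smoke/trace_thread0.csv
```

A run writes one trace CSV per search thread (iteration, sampled time
constants, score, log-likelihood, accepted flag, range widths) and a
`summary.json` with the best configuration.

## Library

```python
from hafit import (
    synth_audiogram, complete_audiogram, HAConfig, TimeConstants,
    amplify, simulate_hl, ProxyScorer, SearchSpec, run_search,
)
from hafit.signals import make_speech_surrogate

ag = synth_audiogram("moderate", seed=7)
cfg = HAConfig(ig65_db=(10, 15, 20, 25, 25), ig85_db=(5, 8, 12, 15, 15),
               ct_db_spl=(45,) * 5)
stimuli = make_speech_surrogate(2, seed=42)
scorer = ProxyScorer(stimuli)

def evaluate(tc):
    degraded = [simulate_hl(amplify(w, cfg.with_tc(tc)), ag) for w in stimuli]
    return scorer.score(degraded)

result = run_search(SearchSpec(n_iterations=50, n_threads=2, seeds=(1, 2)),
                    evaluate)
print(result.best_tc, result.best_result.score_pct)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (range-contraction
closed form, grid legality over full runs, acceptance-rule monotonicity,
oracle parameter recovery, compressor anchor accuracy, attack/release
settling calibration, hearing-loss identity, reproducibility, end-to-end
smoke run). The whole suite takes a few minutes on one CPU.

`scripts/acceptance.py --seed 1 --out results/acceptance.json` runs an
end-to-end sanity check and writes the (empty) numeric-target report — the
source study's headline numbers require an external speech corpus and
recognizer, so acceptance here is property-based.

## Conventions worth knowing

- **Calibration**: a full-scale sinusoid is 100 dB SPL by default; WAV files
  carry a JSON sidecar with the calibration.
- **Detector law**: envelope followers smooth the Hilbert envelope in the dB
  domain; nominal attack/release times are calibrated against settling
  criteria on 55↔90 dB SPL level steps (within 3 dB for attack, 4 dB for
  release).
- **Filterbank**: zero-phase Butterworth crossovers arranged as a
  power-complementary peeling cascade, so the identity configuration
  reconstructs the input within 0.15 dB in-band.
- **Recruitment**: band envelope level L maps to `ceiling − α(ceiling − L)`
  with `α = ceiling / (ceiling − HL_band)` and a 100-dB-SPL ceiling.
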