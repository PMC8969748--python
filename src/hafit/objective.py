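"""Scoring contract for the optimizer, plus desk-scale scorer implementations.

The optimization chain treats the scorer as a black box returning a primary
percentage score and a secondary log-likelihood used only to break ties.
``ProxyScorer`` is an envelope-correlation intelligibility proxy (a STOI-like
construction over the hearing-aid analysis bands); ``OracleScorer`` is a
synthetic objective with a known, certifiable optimum used to test the
search.  A real recognizer can be plugged in by implementing ``Scorer``;
the adapter contract is JSON-lines of ``{path, hypothesis, loglik}`` per
stimulus (not shipped here).
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ha_sim import DEFAULT_CHANNEL_EDGES_KHZ, TimeConstants, analytic_envelope, split_bands
from .signals import Waveform, rms

__all__ = ["ScoreResult", "Scorer", "ProxyScorer", "OracleScorer"]

_SILENCE_RMS = 1e-7
_LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class ScoreResult:
    """Primary objective in percent plus a tie-breaking log-likelihood."""

    score_pct: float
    mean_loglik: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_pct <= 100.0):
            raise ValueError(f"score_pct {self.score_pct} outside [0, 100]")
        if not math.isfinite(self.mean_loglik):
            raise ValueError("mean_loglik must be finite")


class Scorer(abc.ABC):
    """Deterministic, stateless objective over a list of stimuli."""

    @abc.abstractmethod
    def score(self, stimuli: list[Waveform]) -> ScoreResult:
        ...

    @staticmethod
    def _check_stimuli(stimuli: list[Waveform]) -> None:
        if not stimuli:
            raise ValueError("empty stimulus list")
        rates = {w.sample_rate_hz for w in stimuli}
        if len(rates) != 1:
            raise ValueError(f"inconsistent sample rates: {sorted(rates)}")


class ProxyScorer(Scorer):
    """Envelope-correlation intelligibility proxy against clean references.

    Per item and analysis band, the Hilbert envelope is low-pass smoothed,
    decimated to ``env_rate_hz``, cut into half-overlapping ``frame_s`` frames,
    and the Pearson correlation between clean and degraded frame envelopes is
    clipped to [0, 1].  ``score_pct`` is 100 x the grand mean over frames,
    bands and items; ``mean_loglik`` is the mean log of the per-item means
    (a stand-in likelihood that exercises the tie-break path only).

    The construction is invariant to global gain of the degraded signal and
    caps at 100 when degraded == clean.
    """

    def __init__(
        self,
        clean_refs: list[Waveform],
        band_edges_khz=DEFAULT_CHANNEL_EDGES_KHZ,
        frame_s: float = 0.4,
        env_rate_hz: int = 128,
        env_cutoff_hz: float = 32.0,
    ) -> None:
        Scorer._check_stimuli(clean_refs)
        self.clean_refs = list(clean_refs)
        self.band_edges_khz = tuple(band_edges_khz)
        self.frame_s = frame_s
        self.env_rate_hz = env_rate_hz
        self.env_cutoff_hz = env_cutoff_hz
        fs = clean_refs[0].sample_rate_hz
        self._clean_lens = [len(w.samples) for w in clean_refs]
        self._clean_envs = [self._band_envelopes(w.samples, fs) for w in clean_refs]

    def _band_envelopes(self, samples: np.ndarray, fs: int) -> np.ndarray:
        dec = max(1, int(fs // self.env_rate_hz))
        sos = sps.butter(2, self.env_cutoff_hz, btype="low", fs=fs, output="sos")
        envs = []
        for band in split_bands(samples, fs, self.band_edges_khz):
            env = analytic_envelope(band)
            env = sps.sosfiltfilt(sos, env)
            envs.append(env[::dec])
        return np.asarray(envs)

    @staticmethod
    def _frame_corr(a: np.ndarray, b: np.ndarray, frame_len: int) -> list[float]:
        out = []
        hop = max(1, frame_len // 2)
        for start in range(0, max(1, len(a) - frame_len + 1), hop):
            fa = a[start : start + frame_len]
            fb = b[start : start + frame_len]
            sa, sb = np.std(fa), np.std(fb)
            if sa < 1e-12 or sb < 1e-12:
                out.append(1.0 if np.allclose(fa, fb) else 0.0)
                continue
            r = float(np.corrcoef(fa, fb)[0, 1])
            out.append(min(1.0, max(0.0, r)))
        return out

    def score(self, stimuli: list[Waveform]) -> ScoreResult:
        Scorer._check_stimuli(stimuli)
        if len(stimuli) != len(self.clean_refs):
            raise ValueError(
                f"got {len(stimuli)} stimuli for {len(self.clean_refs)} references"
            )
        fs = stimuli[0].sample_rate_hz
        frame_len = max(2, int(round(self.frame_s * self.env_rate_hz)))
        item_vals: list[float] = []
        degenerate = False
        for wf, clean_env, clean_len in zip(stimuli, self._clean_envs, self._clean_lens):
            if len(wf.samples) != clean_len:
                raise ValueError(
                    f"degraded item length {len(wf.samples)} does not match its "
                    f"reference ({clean_len})"
                )
            if rms(wf.samples) < _SILENCE_RMS:
                degenerate = True
                item_vals.append(0.0)
                continue
            deg_env = self._band_envelopes(wf.samples, fs)
            n = min(deg_env.shape[1], clean_env.shape[1])
            corrs: list[float] = []
            for b in range(deg_env.shape[0]):
                corrs.extend(self._frame_corr(clean_env[b, :n], deg_env[b, :n], frame_len))
            item_vals.append(float(np.mean(corrs)) if corrs else 0.0)
        score = 100.0 * float(np.mean(item_vals))
        loglik = float(np.mean([math.log(max(v, _LOG_FLOOR)) for v in item_vals]))
        return ScoreResult(min(100.0, max(0.0, score)), loglik, degenerate=degenerate)


class OracleScorer:
    """Known-optimum objective: 100 minus a weighted L1 distance to a peak.

    ``score_pct = max(0, 100 - sum_ch(|AT - AT*|/w_at + |RT - RT*|/w_rt))`` and
    ``mean_loglik = -distance``, so the floored region still orders correctly
    under the score-then-loglik acceptance rule.  The unique grid maximizer is
    the peak itself.
    """

    def __init__(self, peak_tc: TimeConstants, w_at: float = 10.0, w_rt: float = 100.0) -> None:
        self.peak_tc = peak_tc
        self.w_at = float(w_at)
        self.w_rt = float(w_rt)

    def distance(self, tc: TimeConstants) -> float:
        d = 0.0
        for a, a0 in zip(tc.attack_ms, self.peak_tc.attack_ms):
            d += abs(a - a0) / self.w_at
        for r, r0 in zip(tc.release_ms, self.peak_tc.release_ms):
            d += abs(r - r0) / self.w_rt
        return d

    def score_for(self, tc: TimeConstants) -> ScoreResult:
        d = self.distance(tc)
        return ScoreResult(max(0.0, 100.0 - d), -d)
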