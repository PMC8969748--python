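"""Hearing-loss simulation: loudness recruitment then threshold elevation.

Recruitment expands each band's envelope so that the impaired dynamic range
(ceiling minus hearing loss) is mapped onto the normal one: band levels at
the ceiling are preserved, levels near the elevated threshold are pushed
toward inaudibility.  Threshold elevation is a linear-phase FIR whose
magnitude at each audiometric frequency is minus the hearing loss.

The two stages do not commute; the fixed order here is recruitment first,
filtering second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audiograms import AUDIOMETRIC_FREQS_KHZ, Audiogram
from .ha_sim import DEFAULT_CHANNEL_EDGES_KHZ, analytic_envelope, split_bands
from .signals import Waveform

__all__ = [
    "HLSimConfig",
    "HL_DESIGN_FREQS_KHZ",
    "threshold_filter",
    "apply_threshold_filter",
    "recruit",
    "simulate_hl",
]

#: frequencies at which the elevation filter's response is pinned
HL_DESIGN_FREQS_KHZ = AUDIOMETRIC_FREQS_KHZ


@dataclass(frozen=True)
class HLSimConfig:
    recruitment_bands_khz: tuple[float, ...] = DEFAULT_CHANNEL_EDGES_KHZ
    normal_dynamic_ceiling_db_spl: float = 100.0
    envelope_cutoff_hz: float = 32.0

    def __post_init__(self) -> None:
        edges = tuple(float(v) for v in self.recruitment_bands_khz)
        object.__setattr__(self, "recruitment_bands_khz", edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("recruitment band edges must be ascending")
        if edges[0] < 0.1 or edges[-1] > 8.0:
            raise ValueError("recruitment bands must lie within [0.1, 8] kHz")
        if self.envelope_cutoff_hz <= 0:
            raise ValueError("envelope_cutoff_hz must be positive")


def _require_design_freqs(ag: Audiogram, fs: int) -> None:
    nyq_khz = fs / 2000.0
    missing = [
        f for f in HL_DESIGN_FREQS_KHZ if f < nyq_khz and not ag.has_freq(f)
    ]
    if missing:
        raise ValueError(
            f"audiogram missing design frequencies {missing} kHz; "
            "run complete_audiogram first"
        )


def threshold_filter(ag: Audiogram, sample_rate_hz: int, numtaps: int | None = None) -> np.ndarray:
    """Linear-phase FIR taps attenuating each frequency by the hearing loss there.

    Magnitude at audiometric frequency f is -threshold(f) dB within ~1 dB;
    between design points the response follows log-frequency interpolation.
    """
    _require_design_freqs(ag, sample_rate_hz)
    fs = sample_rate_hz
    if numtaps is None:
        numtaps = 2 * int(0.025 * fs) + 1  # ~50 ms: resolves the 125-Hz design point
    nyq = fs / 2.0
    # dense design grid, log-interpolated loss, flat extension beyond the ends
    grid = np.linspace(0.0, nyq, 2049)
    grid_khz = np.clip(grid / 1000.0, ag.frequencies_khz[0], ag.frequencies_khz[-1])
    loss_db = ag.interp_dbhl(grid_khz)
    gain = 10.0 ** (-loss_db / 20.0)
    return sps.firwin2(numtaps, grid, gain, fs=fs)


def apply_threshold_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply the (odd-length, symmetric) FIR with its group delay removed."""
    return sps.fftconvolve(x, taps, mode="same")


def _band_loss_db(ag: Audiogram, lo_khz: float, hi_khz: float) -> float:
    centre = math.sqrt(lo_khz * hi_khz)
    return float(ag.interp_dbhl(centre)[0])


def recruit(x: Waveform, ag: Audiogram, cfg: HLSimConfig) -> Waveform:
    """Multiband envelope expansion simulating loudness recruitment.

    In each band the envelope level L (dB SPL) maps to
    ``ceiling - alpha * (ceiling - L)`` with ``alpha = ceiling / (ceiling - HL_b)``;
    the ceiling is a fixed point and zero loss gives the identity mapping.
    """
    fs = x.sample_rate_hz
    calib = x.calibration_db_spl_at_fullscale
    ceiling = cfg.normal_dynamic_ceiling_db_spl
    edges = cfg.recruitment_bands_khz
    losses = [
        _band_loss_db(ag, lo, hi) for lo, hi in zip(edges[:-1], edges[1:])
    ]
    for loss, lo, hi in zip(losses, edges[:-1], edges[1:]):
        if loss >= ceiling:
            raise ValueError(
                f"band {lo}-{hi} kHz: hearing loss {loss} dB >= ceiling {ceiling} dB "
                "leaves no residual dynamic range"
            )
    bands = split_bands(x.samples, fs, edges)
    sos_env = sps.butter(2, cfg.envelope_cutoff_hz, btype="low", fs=fs, output="sos")
    out = np.zeros_like(x.samples)
    for band, loss in zip(bands, losses):
        if loss <= 0.0:
            out += band  # alpha == 1: exact envelope identity
            continue
        alpha = ceiling / (ceiling - loss)
        env = analytic_envelope(band)
        env = np.maximum(sps.sosfiltfilt(sos_env, env), 1e-7)
        level = calib + 20.0 * np.log10(env)
        # expand below the ceiling only; levels above it pass unchanged
        gain_db = np.minimum(0.0, (alpha - 1.0) * (level - ceiling))
        out += band * 10.0 ** (gain_db / 20.0)
    return x.with_samples(out)


def simulate_hl(x: Waveform, ag: Audiogram, cfg: HLSimConfig | None = None) -> Waveform:
    """Recruitment followed by the threshold-elevation filter; deterministic."""
    if cfg is None:
        cfg = HLSimConfig()
    _require_design_freqs(ag, x.sample_rate_hz)
    y = recruit(x, ag, cfg)
    taps = threshold_filter(ag, x.sample_rate_hz)
    return y.with_samples(apply_threshold_filter(y.samples, taps))
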