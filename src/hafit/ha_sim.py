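"""Five-channel hearing-aid simulator.

Chain: zero-phase Butterworth analysis filterbank at fixed band edges, per
channel a wide-dynamic-range compressor (envelope follower + static gain
curve) followed by a fast limiter, then summation of the bands.

Level detector convention: the band's Hilbert-magnitude envelope is smoothed
by an asymmetric one-pole filter in the dB domain.  The attack/release time
constants are calibrated so that on a 55->90 dB SPL level step the detector
settles to within 3 dB of the final level after the nominal attack time, and
on a 90->55 dB step to within 4 dB after the nominal release time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signals import Waveform, level_db_spl

__all__ = [
    "TimeConstants",
    "HAConfig",
    "StaticCurve",
    "DEFAULT_CHANNEL_EDGES_KHZ",
    "DEFAULT_TIME_CONSTANTS",
    "derive_static_curve",
    "envelope_follower",
    "compress_channel",
    "limit_channel",
    "amplify",
    "design_filterbank",
    "measure_settling_time",
]

DEFAULT_CHANNEL_EDGES_KHZ = (0.1, 0.7, 1.4, 2.8, 5.6, 8.0)
N_CHANNELS = 5

AT_BOUNDS_MS = (10.0, 500.0)
RT_BOUNDS_MS = (300.0, 2000.0)

#: one-pole dB-domain settling calibration on the 55<->90 dB step:
#: attack = time to within 3 dB of a 35-dB upward step -> tau = AT/ln(35/3);
#: release = time to within 4 dB of a 35-dB downward step -> tau = RT/ln(35/4)
ATTACK_SETTLE_FACTOR = math.log(35.0 / 3.0)
RELEASE_SETTLE_FACTOR = math.log(35.0 / 4.0)

#: Butterworth order per crossover filter (single pass).  Zero-phase
#: application squares the magnitude, so the effective slope is doubled;
#: order 8 keeps adjacent-channel leakage of a centre tone >= 30 dB down
#: while the complementary cascade reconstructs flat.
FILTERBANK_ORDER = 8

_LEVEL_FLOOR_DB = -120.0


@dataclass(frozen=True)
class TimeConstants:
    """Per-channel attack and release times in milliseconds."""

    attack_ms: tuple[float, ...]
    release_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        at = tuple(float(v) for v in self.attack_ms)
        rt = tuple(float(v) for v in self.release_ms)
        object.__setattr__(self, "attack_ms", at)
        object.__setattr__(self, "release_ms", rt)
        if len(at) != len(rt):
            raise ValueError("attack_ms and release_ms must have equal length")
        if any(v <= 0 for v in at + rt):
            raise ValueError("time constants must be positive")
        if any(not (AT_BOUNDS_MS[0] <= v <= AT_BOUNDS_MS[1]) for v in at):
            raise ValueError(f"attack times must lie in {AT_BOUNDS_MS} ms")
        if any(not (RT_BOUNDS_MS[0] <= v <= RT_BOUNDS_MS[1]) for v in rt):
            raise ValueError(f"release times must lie in {RT_BOUNDS_MS} ms")

    @property
    def n_channels(self) -> int:
        return len(self.attack_ms)


#: fixed compression speeds used when no optimization is performed
DEFAULT_TIME_CONSTANTS = TimeConstants(
    attack_ms=(200.0, 100.0, 100.0, 100.0, 100.0),
    release_ms=(2000.0, 1500.0, 1200.0, 1000.0, 1000.0),
)


@dataclass(frozen=True)
class HAConfig:
    """Hearing-aid configuration: gains anchored at 65/85 dB SPL input,
    compression thresholds, limiter, and compressor time constants."""

    ig65_db: tuple[float, ...]
    ig85_db: tuple[float, ...]
    ct_db_spl: tuple[float, ...]
    tc: TimeConstants = DEFAULT_TIME_CONSTANTS
    channel_edges_khz: tuple[float, ...] = DEFAULT_CHANNEL_EDGES_KHZ
    limiter_threshold_db_spl: float = 100.0
    limiter_ratio: float = 10.0
    limiter_attack_ms: float = 5.0
    limiter_release_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("ig65_db", "ig85_db", "ct_db_spl", "channel_edges_khz"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        n = len(self.channel_edges_khz) - 1
        if n != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {n}")
        if any(b <= a for a, b in zip(self.channel_edges_khz, self.channel_edges_khz[1:])):
            raise ValueError("channel edges must be strictly ascending")
        for nm in ("ig65_db", "ig85_db", "ct_db_spl"):
            if len(getattr(self, nm)) != n:
                raise ValueError(f"{nm} must have {n} entries")
        if self.tc.n_channels != n:
            raise ValueError("time constants must have one entry per channel")
        for ch, (g65, g85) in enumerate(zip(self.ig65_db, self.ig85_db)):
            if g65 < g85:
                raise ValueError(
                    f"channel {ch}: ig65 ({g65}) must be >= ig85 ({g85}) "
                    "(compressive or linear gain-level slope)"
                )
            if g85 - g65 <= -20.0:
                raise ValueError(
                    f"channel {ch}: ig85 - ig65 <= -20 dB implies a non-positive "
                    "compression ratio"
                )
        for ch, ct in enumerate(self.ct_db_spl):
            if ct >= 65.0:
                raise ValueError(
                    f"channel {ch}: compression threshold {ct} dB SPL must be "
                    "below the 65-dB anchor"
                )
        if self.limiter_ratio < 10.0:
            raise ValueError("limiter_ratio must be >= 10")

    @property
    def n_channels(self) -> int:
        return len(self.ig65_db)

    def with_tc(self, tc: TimeConstants) -> "HAConfig":
        return replace(self, tc=tc)

    def compression_ratio(self, channel: int) -> float:
        return 20.0 / (20.0 + self.ig85_db[channel] - self.ig65_db[channel])


@dataclass(frozen=True)
class StaticCurve:
    """Piecewise-linear input-level -> gain map (dB -> dB): constant gain below
    the compression threshold, compressive slope through the 65/85 anchors above."""

    ct_db_spl: float
    gain_at_ct_db: float
    ig65_db: float
    slope: float  # d(gain)/d(input level) above CT; equals 1/CR - 1

    def gain_db(self, level_db: np.ndarray | float) -> np.ndarray | float:
        level_db = np.asarray(level_db, dtype=float)
        above = self.ig65_db + self.slope * (level_db - 65.0)
        out = np.where(level_db < self.ct_db_spl, self.gain_at_ct_db, above)
        return out if out.ndim else float(out)

    @property
    def compression_ratio(self) -> float:
        return 1.0 / (1.0 + self.slope)


def derive_static_curve(ig65_db: float, ig85_db: float, ct_db_spl: float) -> StaticCurve:
    """Gain curve through the (65, ig65) and (85, ig85) anchors, linear below CT."""
    if ig85_db - ig65_db <= -20.0:
        raise ValueError("ig85 - ig65 <= -20 dB gives a non-positive compression ratio")
    slope = (ig85_db - ig65_db) / 20.0
    gain_at_ct = ig65_db + slope * (ct_db_spl - 65.0)
    return StaticCurve(ct_db_spl, gain_at_ct, ig65_db, slope)


# --- level detector ---------------------------------------------------------

def _smooth_asym_py(level_in: np.ndarray, alpha_up: float, alpha_dn: float,
                    state: float) -> np.ndarray:
    out = np.empty_like(level_in)
    for i in range(level_in.shape[0]):
        x = level_in[i]
        if x > state:
            state += alpha_up * (x - state)
        else:
            state += alpha_dn * (x - state)
        out[i] = state
    return out


try:  # optional numba acceleration; pure-python fallback is exact but slower
    from numba import njit as _njit

    _smooth_asym = _njit(cache=False)(_smooth_asym_py)
    _smooth_asym(np.zeros(4), 0.5, 0.5, 0.0)  # force compile at import
except Exception:  # pragma: no cover
    _smooth_asym = _smooth_asym_py


def _alpha(time_ms: float, settle_factor: float, fs: int) -> float:
    tau_s = (time_ms * 1e-3) / settle_factor
    return 1.0 - math.exp(-1.0 / (fs * tau_s))


def analytic_envelope(band: np.ndarray) -> np.ndarray:
    """Hilbert-magnitude envelope.

    Computed without zero-padding: padding with silence puts a discontinuity
    at the circular boundary and the resulting ringing leaks into the ends of
    the envelope by tens of dB.
    """
    return np.abs(sps.hilbert(band))


def instantaneous_level_db(band: np.ndarray, fs: int, calibration_db_spl: float) -> np.ndarray:
    """Per-sample band level in dB SPL from the Hilbert-magnitude envelope."""
    env = analytic_envelope(band)
    return calibration_db_spl + 20.0 * np.log10(np.maximum(env, 10.0 ** (_LEVEL_FLOOR_DB / 20.0)))


def envelope_follower(
    band: np.ndarray,
    fs: int,
    attack_ms: float,
    release_ms: float,
    calibration_db_spl: float = 100.0,
) -> np.ndarray:
    """Smoothed per-sample level trajectory (dB SPL) with attack/release dynamics."""
    if attack_ms <= 0 or release_ms <= 0:
        raise ValueError("time constants must be positive")
    if len(band) == 0:
        return np.empty(0)
    level = instantaneous_level_db(band, fs, calibration_db_spl)
    a_up = _alpha(attack_ms, ATTACK_SETTLE_FACTOR, fs)
    a_dn = _alpha(release_ms, RELEASE_SETTLE_FACTOR, fs)
    # seed the state from the first 10 ms so Hilbert edge ringing at sample 0
    # does not bias the (slow) release path for a long stretch
    state0 = float(np.median(level[: max(1, int(0.01 * fs))]))
    return _smooth_asym(np.ascontiguousarray(level, dtype=np.float64), a_up, a_dn, state0)


def compress_channel(
    band: np.ndarray,
    fs: int,
    curve: StaticCurve,
    attack_ms: float,
    release_ms: float,
    calibration_db_spl: float = 100.0,
) -> np.ndarray:
    """Apply the static curve at the followed level, sample by sample."""
    level = envelope_follower(band, fs, attack_ms, release_ms, calibration_db_spl)
    gain_db = curve.gain_db(level)
    return band * 10.0 ** (np.asarray(gain_db) / 20.0)


def limit_channel(
    band: np.ndarray,
    fs: int,
    threshold_db_spl: float,
    ratio: float,
    attack_ms: float = 5.0,
    release_ms: float = 50.0,
    calibration_db_spl: float = 100.0,
) -> np.ndarray:
    """Second series compressor: unity below threshold, ``ratio``:1 above."""
    if not np.isfinite(threshold_db_spl):
        return band  # disabled limiter
    level = envelope_follower(band, fs, attack_ms, release_ms, calibration_db_spl)
    excess = np.maximum(0.0, level - threshold_db_spl)
    gain_db = excess * (1.0 / ratio - 1.0)
    return band * 10.0 ** (gain_db / 20.0)


# --- filterbank -------------------------------------------------------------

def design_filterbank(edges_khz, fs: int, order: int = FILTERBANK_ORDER):
    """Crossover sections for a power-complementary peeling cascade.

    Returns, per interior edge, an (LP, HP) Butterworth pair of the same order
    and cutoff, plus band-limiting HP/LP sections for the outer edges (the
    top LP is omitted when the edge reaches Nyquist).  Applied forward-
    backward the effective magnitude of each pair is |H|^2, and
    ``|H_lp|^2 + |H_hp|^2 == 1`` for Butterworth, so summing the peeled bands
    reconstructs the band-limited input magnitude exactly.
    """
    nyq = fs / 2.0
    lo_hz = edges_khz[0] * 1000.0
    hi_hz = edges_khz[-1] * 1000.0
    if lo_hz >= nyq:
        raise ValueError(f"channel edge {edges_khz[0]} kHz at or above Nyquist")
    outer_hp = sps.butter(order, lo_hz, btype="high", fs=fs, output="sos")
    outer_lp = (
        None if hi_hz >= nyq * 0.999
        else sps.butter(order, hi_hz, btype="low", fs=fs, output="sos")
    )
    pairs = []
    for edge_khz in edges_khz[1:-1]:
        f = edge_khz * 1000.0
        if f >= nyq:
            raise ValueError(f"channel edge {edge_khz} kHz at or above Nyquist")
        pairs.append(
            (
                sps.butter(order, f, btype="low", fs=fs, output="sos"),
                sps.butter(order, f, btype="high", fs=fs, output="sos"),
            )
        )
    return outer_hp, outer_lp, pairs


def split_bands(x: np.ndarray, fs: int, edges_khz=DEFAULT_CHANNEL_EDGES_KHZ,
                order: int = FILTERBANK_ORDER) -> list[np.ndarray]:
    """Analysis: peel channels off bottom-up with complementary LP/HP pairs."""
    outer_hp, outer_lp, pairs = design_filterbank(edges_khz, fs, order)
    rest = sps.sosfiltfilt(outer_hp, x)
    if outer_lp is not None:
        rest = sps.sosfiltfilt(outer_lp, rest)
    bands = []
    for sos_lp, sos_hp in pairs:
        bands.append(sps.sosfiltfilt(sos_lp, rest))
        rest = sps.sosfiltfilt(sos_hp, rest)
    bands.append(rest)
    return bands


def amplify(x: Waveform, cfg: HAConfig) -> Waveform:
    """Full simulator: analysis, per-channel WDRC + limiter, resynthesis.

    Deterministic; zero-phase filtering preserves length and alignment.
    """
    fs = x.sample_rate_hz
    calib = x.calibration_db_spl_at_fullscale
    bands = split_bands(x.samples, fs, cfg.channel_edges_khz)
    out = np.zeros_like(x.samples)
    for ch, band in enumerate(bands):
        curve = derive_static_curve(cfg.ig65_db[ch], cfg.ig85_db[ch], cfg.ct_db_spl[ch])
        y = compress_channel(
            band, fs, curve, cfg.tc.attack_ms[ch], cfg.tc.release_ms[ch], calib
        )
        y = limit_channel(
            y, fs, cfg.limiter_threshold_db_spl, cfg.limiter_ratio,
            cfg.limiter_attack_ms, cfg.limiter_release_ms, calib,
        )
        out += y
    return x.with_samples(out)


# --- measurement ------------------------------------------------------------

def measure_settling_time(
    level_db: np.ndarray,
    fs: int,
    t_step_s: float,
    target_db: float,
    tol_db: float,
) -> float:
    """Seconds from the step until the trajectory enters (and stays within)
    ``tol_db`` of ``target_db``.  Returns inf if it never settles."""
    i0 = int(round(t_step_s * fs))
    tail = np.abs(np.asarray(level_db)[i0:] - target_db) <= tol_db
    if not tail.any():
        return math.inf
    outside = np.nonzero(~tail)[0]
    first_settled = 0 if len(outside) == 0 else (
        math.inf if outside[-1] == len(tail) - 1 else outside[-1] + 1
    )
    if first_settled is math.inf:
        return math.inf
    return first_settled / fs
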