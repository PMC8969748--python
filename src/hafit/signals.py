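"""Calibrated test-signal generation and WAV input/output.

All waveforms carry an explicit digital calibration: the dB SPL level
assigned to a full-scale sinusoid (amplitude 1.0).  Under that convention a
sinusoid of amplitude ``a`` sits at ``calibration + 20*log10(a)`` dB SPL,
and an arbitrary signal's level is measured from its RMS relative to the
RMS of a full-scale sinusoid (``1/sqrt(2)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "DEFAULT_CALIBRATION_DB_SPL",
    "DEFAULT_SAMPLE_RATE_HZ",
    "rms",
    "level_db_spl",
    "make_tone",
    "make_level_step",
    "make_speech_surrogate",
    "write_wav",
    "read_wav",
]

DEFAULT_CALIBRATION_DB_SPL = 100.0
DEFAULT_SAMPLE_RATE_HZ = 22050
MIN_SAMPLE_RATE_HZ = 16000

_FULL_SCALE_RMS = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class Waveform:
    """A mono waveform with sampling rate and digital SPL calibration.

    ``samples`` are full-scale-relative (dimensionless).  Generated signals
    keep ``|sample| <= 1``; intermediate processing stages may exceed unity
    transiently (floating-point headroom) — peak legality is re-enforced when
    writing WAV files.
    """

    samples: np.ndarray
    sample_rate_hz: int
    calibration_db_spl_at_fullscale: float = DEFAULT_CALIBRATION_DB_SPL
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if self.sample_rate_hz < MIN_SAMPLE_RATE_HZ:
            raise ValueError(
                f"sample_rate_hz must be >= {MIN_SAMPLE_RATE_HZ}, "
                f"got {self.sample_rate_hz}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0

    def rms_db_spl(self) -> float:
        """Broadband RMS level in dB SPL under this waveform's calibration."""
        return level_db_spl(self.samples, self.calibration_db_spl_at_fullscale)

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        return 0.0
    return float(np.sqrt(np.mean(x * x)))


def level_db_spl(x: np.ndarray, calibration_db_spl: float = DEFAULT_CALIBRATION_DB_SPL) -> float:
    """RMS level of ``x`` in dB SPL: full-scale sine (RMS 1/sqrt(2)) == calibration."""
    r = rms(x)
    if r <= 0.0:
        return -np.inf
    return calibration_db_spl + 20.0 * np.log10(r / _FULL_SCALE_RMS)


def _amplitude_for_level(level_db: float, calibration_db_spl: float) -> float:
    amp = 10.0 ** ((level_db - calibration_db_spl) / 20.0)
    if amp > 1.0 + 1e-9:
        raise ValueError(
            f"requested level {level_db} dB SPL exceeds full scale "
            f"({calibration_db_spl} dB SPL)"
        )
    return min(amp, 1.0)


def make_tone(
    freq_hz: float,
    level_db_spl: float,
    duration_s: float,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    calibration_db_spl: float = DEFAULT_CALIBRATION_DB_SPL,
    phase_rad: float = 0.0,
) -> Waveform:
    """A sinusoid whose RMS level equals ``level_db_spl`` under the calibration."""
    if freq_hz >= sample_rate_hz / 2:
        raise ValueError(
            f"tone frequency {freq_hz} Hz is at or above Nyquist "
            f"({sample_rate_hz / 2} Hz)"
        )
    amp = _amplitude_for_level(level_db_spl, calibration_db_spl)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    samples = amp * np.sin(2 * np.pi * freq_hz * t + phase_rad)
    return Waveform(samples, sample_rate_hz, calibration_db_spl, label=f"tone{freq_hz:g}Hz")


def make_level_step(
    freq_hz: float,
    level1_db_spl: float,
    level2_db_spl: float,
    t_step_s: float,
    duration_s: float,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    calibration_db_spl: float = DEFAULT_CALIBRATION_DB_SPL,
) -> Waveform:
    """A phase-continuous sinusoid at ``level1`` before ``t_step_s``, ``level2`` after."""
    if freq_hz >= sample_rate_hz / 2:
        raise ValueError("tone frequency at or above Nyquist")
    a1 = _amplitude_for_level(level1_db_spl, calibration_db_spl)
    a2 = _amplitude_for_level(level2_db_spl, calibration_db_spl)
    n = int(round(duration_s * sample_rate_hz))
    n_step = int(round(t_step_s * sample_rate_hz))
    n_step = max(0, min(n, n_step))
    t = np.arange(n) / sample_rate_hz
    carrier = np.sin(2 * np.pi * freq_hz * t)
    amp = np.where(np.arange(n) < n_step, a1, a2)
    return Waveform(amp * carrier, sample_rate_hz, calibration_db_spl, label="level_step")


# --- speech surrogate -------------------------------------------------------

#: formant centre frequencies (Hz) drawn per vowel-like segment
_FORMANT_POOL = (
    (300.0, 2300.0, 3000.0),
    (400.0, 2000.0, 2600.0),
    (500.0, 1500.0, 2500.0),
    (700.0, 1200.0, 2600.0),
    (350.0, 800.0, 2400.0),
)


def _vowel_segment(rng, n, fs, f0_hz):
    """Harmonic complex shaped by a random formant triple."""
    from scipy import signal as sps

    t = np.arange(n) / fs
    n_harm = int(min(5000.0, fs / 2 * 0.9) // f0_hz)
    harmonics = np.arange(1, n_harm + 1)[:, None] * f0_hz
    phases = rng.uniform(0, 2 * np.pi, size=(n_harm, 1))
    x = np.sum(np.sin(2 * np.pi * harmonics * t[None, :] + phases) / harmonics, axis=0)
    formants = _FORMANT_POOL[rng.integers(len(_FORMANT_POOL))]
    for fc in formants:
        if fc < fs / 2 * 0.9:
            sos = sps.butter(2, [fc * 0.8, fc * 1.25], btype="band", fs=fs, output="sos")
            x = x + 4.0 * sps.sosfilt(sos, x)
    return x


def _consonant_segment(rng, n, fs):
    """High-pass filtered noise burst."""
    from scipy import signal as sps

    x = rng.standard_normal(n)
    sos = sps.butter(2, 1800.0, btype="high", fs=fs, output="sos")
    return sps.sosfilt(sos, x)


def make_speech_surrogate(
    n_items: int,
    seed: int,
    duration_s: float = 1.2,
    level_db_spl: float = 65.0,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    calibration_db_spl: float = DEFAULT_CALIBRATION_DB_SPL,
    cv_offset_db: float = -12.0,
    syllable_rate_hz: float = 4.0,
) -> list[Waveform]:
    """Seeded speech-like stimuli: alternating vowel-like (harmonic, formant
    filtered) and consonant-like (noise burst) segments at ``syllable_rate_hz``,
    with consonants ``cv_offset_db`` dB below vowels.

    Deterministic per ``(item index, seed)``.
    """
    fs = sample_rate_hz
    items: list[Waveform] = []
    for idx in range(n_items):
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        n_total = int(round(duration_s * fs))
        # one syllable = consonant (1/3) + vowel (2/3)
        n_syll = int(round(duration_s * syllable_rate_hz))
        n_syll = max(1, n_syll)
        seg = np.zeros(n_total)
        bounds = np.linspace(0, n_total, n_syll + 1).astype(int)
        ramp_n = max(8, int(0.005 * fs))
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            n_seg = s1 - s0
            n_c = n_seg // 3
            f0 = rng.uniform(100.0, 220.0)
            c = _consonant_segment(rng, n_c, fs)
            v = _vowel_segment(rng, n_seg - n_c, fs, f0)
            c = c / (rms(c) + 1e-12) * 10.0 ** (cv_offset_db / 20.0)
            v = v / (rms(v) + 1e-12)
            piece = np.concatenate([c, v])
            win = np.ones(n_seg)
            k = min(ramp_n, n_seg // 2)
            win[:k] = np.sin(np.linspace(0, np.pi / 2, k)) ** 2
            win[-k:] = win[:k][::-1]
            seg[s0:s1] = piece * win
        target_rms = _FULL_SCALE_RMS * 10.0 ** ((level_db_spl - calibration_db_spl) / 20.0)
        seg = seg / (rms(seg) + 1e-12) * target_rms
        peak = np.max(np.abs(seg))
        if peak > 1.0:
            seg = seg / peak  # keep full-scale legality; level error logged via rms
        items.append(
            Waveform(seg, fs, calibration_db_spl, label=f"surrogate[{idx}]")
        )
    return items


# --- WAV + sidecar calibration ---------------------------------------------

def write_wav(wf: Waveform, path: str | Path) -> None:
    """Write float32 mono WAV plus a ``.json`` calibration sidecar."""
    path = Path(path)
    samples = np.clip(wf.samples, -1.0, 1.0).astype(np.float32)
    wavfile.write(path, wf.sample_rate_hz, samples)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "calibration_db_spl_at_fullscale": wf.calibration_db_spl_at_fullscale,
                "label": wf.label,
            }
        )
    )


def read_wav(path: str | Path, calibration_db_spl: float | None = None) -> Waveform:
    """Read a mono WAV; calibration from the sidecar JSON if present."""
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    else:
        samples = data.astype(np.float64)
    label = path.stem
    if calibration_db_spl is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            calibration_db_spl = float(meta["calibration_db_spl_at_fullscale"])
            label = meta.get("label", label)
        else:
            calibration_db_spl = DEFAULT_CALIBRATION_DB_SPL
    return Waveform(samples, int(fs), calibration_db_spl, label=label)
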