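"""Audiometric profiles: validation, cubic completion, PTA, synthesis, CSV I/O."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Audiogram",
    "AUDIOMETRIC_FREQS_KHZ",
    "PTA_FREQS_KHZ",
    "SEVERITY_PTA_BANDS_DBHL",
    "complete_audiogram",
    "pta",
    "synth_audiogram",
    "load_audiogram_csv",
    "save_audiogram_csv",
]

FREQ_MIN_KHZ = 0.125
FREQ_MAX_KHZ = 8.0
THRESH_MIN_DBHL = -10.0
THRESH_MAX_DBHL = 120.0

#: standard audiometric frequencies covering the band of interest
AUDIOMETRIC_FREQS_KHZ = (0.125, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)

#: frequencies entering the pure-tone average
PTA_FREQS_KHZ = (0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0)

#: PTA bands (dB HL) defining the synthetic-audiogram severity classes
SEVERITY_PTA_BANDS_DBHL = {
    "mild": (20.0, 34.0),
    "moderate": (35.0, 49.0),
    "moderately_severe": (50.0, 64.0),
    "severe": (65.0, 80.0),
}

_FREQ_ATOL = 1e-9


@dataclass(frozen=True)
class Audiogram:
    """Pure-tone thresholds (dB HL) at strictly increasing frequencies (kHz)."""

    frequencies_khz: tuple[float, ...]
    thresholds_dbhl: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_khz)
        thrs = tuple(float(t) for t in self.thresholds_dbhl)
        object.__setattr__(self, "frequencies_khz", freqs)
        object.__setattr__(self, "thresholds_dbhl", thrs)
        if len(freqs) != len(thrs):
            raise ValueError("frequencies and thresholds must have equal length")
        if len(freqs) < 2:
            raise ValueError("audiogram needs at least 2 points")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be strictly increasing")
        if freqs[0] < FREQ_MIN_KHZ - _FREQ_ATOL or freqs[-1] > FREQ_MAX_KHZ + _FREQ_ATOL:
            raise ValueError(
                f"frequencies must lie within [{FREQ_MIN_KHZ}, {FREQ_MAX_KHZ}] kHz"
            )
        for t in thrs:
            if not (THRESH_MIN_DBHL <= t <= THRESH_MAX_DBHL):
                raise ValueError(
                    f"threshold {t} dB HL outside "
                    f"[{THRESH_MIN_DBHL}, {THRESH_MAX_DBHL}]"
                )

    def threshold_at(self, freq_khz: float) -> float:
        """Exact threshold at ``freq_khz``; KeyError if the frequency is absent."""
        for f, t in zip(self.frequencies_khz, self.thresholds_dbhl):
            if abs(f - freq_khz) <= _FREQ_ATOL * max(1.0, freq_khz):
                return t
        raise KeyError(
            f"frequency {freq_khz} kHz not in audiogram; run complete_audiogram first"
        )

    def has_freq(self, freq_khz: float) -> bool:
        try:
            self.threshold_at(freq_khz)
            return True
        except KeyError:
            return False

    def interp_dbhl(self, freqs_khz) -> np.ndarray:
        """Piecewise-linear interpolation in log2 frequency (flat beyond the ends)."""
        x = np.log2(np.asarray(self.frequencies_khz, dtype=float))
        y = np.asarray(self.thresholds_dbhl, dtype=float)
        q = np.log2(np.atleast_1d(np.asarray(freqs_khz, dtype=float)))
        return np.interp(q, x, y)


def complete_audiogram(ag: Audiogram, target_freqs_khz) -> Audiogram:
    """Fill missing frequencies with a degree-3 least-squares polynomial fit.

    The cubic is fitted to (log2 frequency, threshold) over all input points;
    original thresholds are retained verbatim, fitted values are clamped to
    the legal dB HL range.  Idempotent when all targets are already present.
    """
    targets = [float(f) for f in target_freqs_khz]
    for f in targets:
        if f < FREQ_MIN_KHZ - _FREQ_ATOL or f > FREQ_MAX_KHZ + _FREQ_ATOL:
            raise ValueError(
                f"target frequency {f} kHz outside the audiometric band "
                f"[{FREQ_MIN_KHZ}, {FREQ_MAX_KHZ}] kHz"
            )
    missing = [f for f in targets if not ag.has_freq(f)]
    if not missing:
        return ag
    if len(ag.frequencies_khz) < 4:
        raise ValueError("insufficient points for cubic fit (need >= 4)")

    x = np.log2(np.asarray(ag.frequencies_khz, dtype=float))
    y = np.asarray(ag.thresholds_dbhl, dtype=float)
    # centre the abscissa for conditioning; fit exact degree-3 LS polynomial
    x0 = x.mean()
    coeffs = np.polynomial.polynomial.polyfit(x - x0, y, deg=3)

    new_points = {f: t for f, t in zip(ag.frequencies_khz, ag.thresholds_dbhl)}
    for f in missing:
        val = np.polynomial.polynomial.polyval(np.log2(f) - x0, coeffs)
        new_points[f] = float(np.clip(val, THRESH_MIN_DBHL, THRESH_MAX_DBHL))
    freqs = tuple(sorted(new_points))
    return Audiogram(freqs, tuple(new_points[f] for f in freqs), label=ag.label)


def pta(ag: Audiogram, freqs_khz=PTA_FREQS_KHZ) -> float:
    """Arithmetic mean threshold over exactly the requested frequencies."""
    return float(np.mean([ag.threshold_at(f) for f in freqs_khz]))


def synth_audiogram(severity: str, seed: int) -> Audiogram:
    """Seeded sloping audiogram whose PTA falls in the severity's band.

    Shape: flat-to-gently-rising below 0.5 kHz, then a random high-frequency
    slope (6-14 dB/octave) with small jitter, shifted so the 7-frequency PTA
    lands uniformly inside the severity band, and clamped to legal limits.
    """
    if severity not in SEVERITY_PTA_BANDS_DBHL:
        raise ValueError(
            f"unknown severity {severity!r}; expected one of "
            f"{sorted(SEVERITY_PTA_BANDS_DBHL)}"
        )
    lo, hi = SEVERITY_PTA_BANDS_DBHL[severity]
    sev_idx = sorted(SEVERITY_PTA_BANDS_DBHL).index(severity)
    rng = np.random.default_rng(np.random.SeedSequence([sev_idx, seed]))
    target_pta = rng.uniform(lo, hi)
    slope_db_per_oct = rng.uniform(6.0, 14.0)
    freqs = np.asarray(AUDIOMETRIC_FREQS_KHZ)
    shape = slope_db_per_oct * np.maximum(0.0, np.log2(freqs / 0.5))
    shape += 2.0 * np.maximum(0.0, np.log2(0.5 / freqs))  # slight low-freq rise
    jitter = rng.normal(0.0, 1.5, size=len(freqs))
    raw = shape + jitter
    raw = np.maximum.accumulate(raw - 3.0) + 3.0  # monotone up to 3 dB of jitter
    pta_mask = np.isin(freqs, PTA_FREQS_KHZ)
    raw = raw + (target_pta - raw[pta_mask].mean())
    thr = np.clip(raw, THRESH_MIN_DBHL, THRESH_MAX_DBHL)
    return Audiogram(
        tuple(freqs), tuple(float(t) for t in thr), label=f"synth-{severity}-{seed}"
    )


def load_audiogram_csv(path: str | Path, label: str | None = None) -> Audiogram:
    """Two-column CSV (frequency_khz, threshold_dbhl) with a header row."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"{path}: expected header 'frequency_khz,threshold_dbhl'")
        rows = [(float(r[0]), float(r[1])) for r in reader if r]
    rows.sort()
    return Audiogram(
        tuple(f for f, _ in rows),
        tuple(t for _, t in rows),
        label=label if label is not None else path.stem,
    )


def save_audiogram_csv(ag: Audiogram, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency_khz", "threshold_dbhl"])
        for f, t in zip(ag.frequencies_khz, ag.thresholds_dbhl):
            writer.writerow([f"{f:g}", f"{t:g}"])
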