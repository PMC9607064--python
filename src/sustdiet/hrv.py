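"""R-R interval preprocessing and spectral heart-rate-variability analysis.

Pipeline: (1) flag artifact beats whose interval deviates from a local
moving median by more than a threshold (default 0.45 s); (2) replace
flagged intervals by cubic-spline interpolation over clean neighbours;
(3) resample the tachogram to an equidistant 4 Hz grid by cubic spline;
(4) estimate the power spectral density by Welch's method (overlapping
Hann windows, linear detrend); (5) integrate the high-frequency band
(0.15-0.4 Hz), reporting absolute power (s^2) and normalized units
(% of total power above 0.04 Hz).

Six-minute supine recordings are the intended input, so the default Welch
window is 120 s with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "RRSeries",
    "PSDEstimate",
    "BandPower",
    "detect_artifacts",
    "correct_artifacts",
    "resample_tachogram",
    "welch_psd",
    "band_power",
    "analyze_rr",
    "read_rr_file",
    "write_rr_file",
]

HF_BAND = (0.15, 0.40)
VLF_CUTOFF_HZ = 0.04
DEFAULT_THRESHOLD_S = 0.45
DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_WINDOW_S = 120.0
DEFAULT_OVERLAP = 0.5


@dataclass
class RRSeries:
    """Successive inter-beat intervals (s) with cumulative beat times."""

    rr: np.ndarray
    artifact_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if (self.rr <= 0).any():
            raise ValueError("all R-R intervals must be positive")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.rr.size, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.size != self.rr.size:
                raise ValueError("flags must match the number of beats")

    @property
    def beat_times(self) -> np.ndarray:
        return np.cumsum(self.rr)

    @property
    def duration(self) -> float:
        return float(self.rr.sum())


@dataclass
class PSDEstimate:
    """Welch PSD on a non-negative ascending frequency grid (power in s^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    resample_rate: float
    window_length: float
    overlap: float

    @property
    def nyquist(self) -> float:
        return self.resample_rate / 2.0


@dataclass
class BandPower:
    band: tuple[float, float]
    absolute: float  # s^2
    normalized: float  # % of total power above the VLF cutoff

    @property
    def absolute_ms2(self) -> float:
        return self.absolute * 1e6


def detect_artifacts(rr: RRSeries, threshold: float = DEFAULT_THRESHOLD_S) -> np.ndarray:
    """Flag beats deviating from the 11-beat surrounding moving median.

    The local average is the median of up to 11 neighbouring intervals
    (5 each side), excluding the beat itself.
    """
    x = rr.rr
    n = x.size
    if n < 12:
        raise ValueError(f"artifact detection requires >= 12 beats, got {n}")
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - 5), min(n, i + 6)
        window = np.delete(x[lo:hi], i - lo)
        flags[i] = abs(x[i] - np.median(window)) > threshold
    return flags


def correct_artifacts(rr: RRSeries, flags: np.ndarray | None = None) -> RRSeries:
    """Replace flagged intervals by cubic-spline interpolation over clean beats.

    Beat times of clean beats anchor the spline; total duration is preserved
    up to the interpolation error at the flagged beats.
    """
    flags = rr.artifact_flags if flags is None else np.asarray(flags, dtype=bool)
    if flags.all():
        raise ValueError("cannot correct a series with every beat flagged")
    if not flags.any():
        return RRSeries(rr.rr.copy(), np.zeros(rr.rr.size, dtype=bool))
    t = rr.beat_times
    clean = ~flags
    if clean.sum() < 4:
        raise ValueError("too few clean beats for spline correction")
    spline = CubicSpline(t[clean], rr.rr[clean])
    corrected = rr.rr.copy()
    corrected[flags] = spline(t[flags])
    corrected = np.clip(corrected, 1e-3, None)
    return RRSeries(corrected, np.zeros(corrected.size, dtype=bool))


def resample_tachogram(
    rr: RRSeries, rate: float = DEFAULT_RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample RR(t) onto an equidistant grid (default 4 Hz)."""
    if rr.rr.size < 4:
        raise ValueError("resampling requires >= 4 beats")
    t = rr.beat_times
    spline = CubicSpline(t, rr.rr)
    grid = np.arange(t[0], t[-1], 1.0 / rate)
    return grid, spline(grid)


def welch_psd(
    samples: np.ndarray,
    rate: float = DEFAULT_RESAMPLE_HZ,
    window_length: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    detrend: str = "linear",
) -> PSDEstimate:
    """Averaged modified periodogram (Hann window) of the resampled tachogram."""
    samples = np.asarray(samples, dtype=float)
    nperseg = int(round(window_length * rate))
    if nperseg > samples.size:
        raise ValueError(
            f"window of {nperseg} samples exceeds signal length {samples.size}"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if detrend not in ("linear", "none"):
        raise ValueError("detrend must be 'linear' or 'none'")
    freqs, power = signal.welch(
        samples,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="linear" if detrend == "linear" else False,
        scaling="density",
    )
    return PSDEstimate(
        freqs=freqs,
        power=power,
        resample_rate=rate,
        window_length=window_length,
        overlap=overlap,
    )


def band_power(psd: PSDEstimate, band: tuple[float, float] = HF_BAND) -> BandPower:
    """Trapezoidal band power, absolute (s^2) and normalized (% above VLF)."""
    lo, hi = band
    if not 0 <= lo < hi <= psd.nyquist + 1e-9:
        raise ValueError(f"band {band} outside [0, Nyquist={psd.nyquist}]")
    in_band = (psd.freqs >= lo) & (psd.freqs <= hi)
    if in_band.sum() < 2:
        raise ValueError("fewer than two frequency bins inside the band")
    absolute = float(np.trapezoid(psd.power[in_band], psd.freqs[in_band]))
    above_vlf = psd.freqs >= VLF_CUTOFF_HZ
    total = float(np.trapezoid(psd.power[above_vlf], psd.freqs[above_vlf]))
    normalized = 100.0 * absolute / total if total > 0 else 0.0
    return BandPower(band=(lo, hi), absolute=absolute, normalized=normalized)


def analyze_rr(
    rr: RRSeries,
    threshold: float = DEFAULT_THRESHOLD_S,
    rate: float = DEFAULT_RESAMPLE_HZ,
    window_length: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    band: tuple[float, float] = HF_BAND,
) -> dict:
    """Full pipeline: artifact correction -> tachogram -> Welch -> HF power."""
    flags = detect_artifacts(rr, threshold=threshold)
    cleaned = correct_artifacts(rr, flags) if flags.any() else rr
    _, samples = resample_tachogram(cleaned, rate=rate)
    window_length = min(window_length, samples.size / rate)
    psd = welch_psd(samples, rate=rate, window_length=window_length, overlap=overlap)
    bp = band_power(psd, band=band)
    return {
        "hf_abs_s2": bp.absolute,
        "hf_abs_ms2": bp.absolute_ms2,
        "hf_nu": bp.normalized,
        "artifacts_pct": 100.0 * float(flags.mean()),
        "n_beats": int(rr.rr.size),
    }


def read_rr_file(path: str | Path, unit: str = "ms") -> RRSeries:
    """Read a plain-text RR file, one interval per line (ms by default)."""
    values = np.loadtxt(Path(path), dtype=float, ndmin=1)
    if unit == "ms":
        values = values / 1000.0
    elif unit != "s":
        raise ValueError("unit must be 'ms' or 's'")
    return RRSeries(values)


def write_rr_file(rr: RRSeries, path: str | Path, unit: str = "ms") -> None:
    values = rr.rr * 1000.0 if unit == "ms" else rr.rr
    np.savetxt(Path(path), values, fmt="%.3f")
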