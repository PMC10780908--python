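"""Surface-EMG fatigue metrics.

Implements the four signal-level efficiency measures used throughout the
package: mean absolute value (MAV, the average rectified amplitude),
instantaneous median frequency (IMDF) of the short-time power spectrum,
the median-power trend over a fatiguing contraction, and the accumulated
squared-activation fatigue integral (FAT).

During a sustained contraction approaching exhaustion the sEMG amplitude
grows (additional motor-unit recruitment) while the power spectrum
compresses toward low frequencies (conduction-velocity slow-down), so MAV
trends upward and IMDF trends downward; those two signatures are what the
trend helpers quantify.

All functions accept plain NumPy arrays or the small dataclass containers
defined here; amplitudes are in mV unless normalized to %MVIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, signal

log = logging.getLogger(__name__)

#: Electrode sites, in recording order: upper/middle trapezius, middle /
#: posterior / anterior deltoid, and brachioradialis (forearm; not a
#: shoulder-elevation muscle, so it is exempt from shoulder-fatigue checks).
CHANNELS: tuple[str, ...] = ("UTRA", "MTRA", "MDEL", "PDEL", "ADEL", "BRD")
SHOULDER_CHANNELS: tuple[str, ...] = CHANNELS[:5]


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing chain parameters.

    Band-pass 20-450 Hz (4th-order zero-phase Butterworth) removes motion
    artifact and out-of-band noise; the rectified signal is smoothed with a
    6 Hz low-pass to form the linear envelope before MVIC normalization.
    """

    band_hz: tuple[float, float] = (20.0, 450.0)
    order: int = 4
    envelope_cutoff_hz: float = 6.0
    envelope_order: int = 4


@dataclass
class EmgRecording:
    """Multi-channel raw sEMG: ``data`` has shape (n_channels, n_samples)."""

    channels: tuple[str, ...]
    data: np.ndarray
    sample_rate: float
    units: str = "mV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows for {len(self.channels)} channel labels"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class ActivationSet:
    """Normalized activation envelopes sigma_m(t), one row per channel.

    Values are dimensionless fractions of MVIC; small overshoot above 1 is
    tolerated (submaximal normalization), negatives are not.
    """

    channels: tuple[str, ...]
    data: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if np.any(self.data < 0):
            raise ValueError("activations must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class Spectrogram:
    """Short-time power spectral density P(t, omega).

    ``power`` has shape (n_freqs, n_times) with density scaling
    (units^2 / Hz); frequencies ascend and are bounded by Nyquist.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must have shape (n_freqs, n_times)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency bins must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")


@dataclass
class MeasureResult:
    """One computed efficiency measure (ids 1-12) with provenance."""

    measure_id: int
    value: float
    units: str
    channel: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= int(self.measure_id) <= 12:
            raise ValueError(f"invalid measure id {self.measure_id}")


@dataclass(frozen=True)
class TrendResult:
    """Least-squares slope (per second, or per window if no times given)
    and last-k/first-k window-mean ratio of a per-window trace."""

    slope: float
    ratio: float
    n_windows: int
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# Measure 1: mean absolute value


def mav(x: Sequence[float] | np.ndarray) -> float:
    """Mean absolute value (average rectified value) of a signal window."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("mav is undefined for an empty signal")
    return float(np.mean(np.abs(x)))


def mav_trend(
    x: np.ndarray, sample_rate: float, window_s: float = 0.5, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed MAV trace: (window-center times, MAV per window)."""
    x = np.asarray(x, dtype=float).ravel()
    nper = int(round(window_s * sample_rate))
    if nper < 1 or nper > x.size:
        raise ValueError("window does not fit the signal")
    hop = max(1, nper - int(round(overlap * nper)))
    starts = np.arange(0, x.size - nper + 1, hop)
    idx = starts[:, None] + np.arange(nper)[None, :]
    vals = np.mean(np.abs(x[idx]), axis=1)
    times = (starts + (nper - 1) / 2.0) / sample_rate
    return times, vals


# ---------------------------------------------------------------------------
# Preprocessing (band-pass -> rectify -> envelope -> MVIC normalization)


def preprocess_emg(
    raw: EmgRecording,
    mvic_levels: Mapping[str, float],
    config: FilterConfig = FilterConfig(),
) -> ActivationSet:
    """Convert raw sEMG to normalized activation envelopes.

    ``mvic_levels`` gives, per channel, the envelope amplitude (same units
    as the recording) measured during a maximum voluntary isometric
    contraction; the filtered envelope is divided by it so a maximal effort
    maps to activation ~= 1.
    """
    missing = [c for c in raw.channels if c not in mvic_levels]
    if missing:
        raise ValueError(f"missing MVIC levels for channels {missing}")
    levels = np.array([mvic_levels[c] for c in raw.channels], dtype=float)
    if np.any(levels <= 0):
        raise ValueError("MVIC levels must be positive")
    lo, hi = config.band_hz
    if raw.sample_rate < 2.0 * hi:
        raise ValueError(
            f"sample rate {raw.sample_rate} Hz below twice the band-pass "
            f"upper edge {hi} Hz"
        )
    sos_bp = signal.butter(
        config.order, [lo, hi], btype="bandpass", fs=raw.sample_rate, output="sos"
    )
    sos_env = signal.butter(
        config.envelope_order,
        config.envelope_cutoff_hz,
        btype="lowpass",
        fs=raw.sample_rate,
        output="sos",
    )
    band = signal.sosfiltfilt(sos_bp, raw.data, axis=1)
    env = signal.sosfiltfilt(sos_env, np.abs(band), axis=1)
    env = np.clip(env, 0.0, None)
    return ActivationSet(raw.channels, env / levels[:, None], raw.sample_rate)


# ---------------------------------------------------------------------------
# Measures 2-3: short-time PSD, median frequency, median-power trend


def time_dependent_psd(
    x: np.ndarray, sample_rate: float, window_s: float = 0.5, overlap: float = 0.5
) -> Spectrogram:
    """Hann-windowed short-time PSD (density scaling, units^2/Hz)."""
    x = np.asarray(x, dtype=float).ravel()
    nper = int(round(window_s * sample_rate))
    if nper > x.size:
        raise ValueError("window longer than signal")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nover = int(round(overlap * nper))
    freqs, times, power = signal.spectrogram(
        x,
        fs=sample_rate,
        window="hann",
        nperseg=nper,
        noverlap=nover,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(times, freqs, power, window_s, overlap)


def imdf(spec: Spectrogram) -> np.ndarray:
    """Instantaneous median frequency per window (Hz).

    For each window the IMDF splits the integrated power spectrum into equal
    halves; computed by cumulative trapezoidal integration over frequency and
    linear interpolation between bins. Windows with zero total power are
    returned as NaN with a logged warning.
    """
    cum = integrate.cumulative_trapezoid(spec.power, spec.freqs, axis=0, initial=0.0)
    total = cum[-1]
    out = np.full(spec.times.size, np.nan)
    dead = total <= 0
    if np.any(dead):
        log.warning("imdf: %d zero-power window(s) returned as NaN", int(dead.sum()))
    alive = np.nonzero(~dead)[0]
    half = 0.5 * total
    for j in alive:
        out[j] = float(np.interp(half[j], cum[:, j], spec.freqs))
    return out


def median_power(spec: Spectrogram, definition: str = "total") -> np.ndarray:
    """Per-window spectral power trace for the median-power fatigue trend.

    ``definition='total'`` (default) integrates the PSD over frequency per
    window; ``definition='median_psd'`` takes the median PSD ordinate instead.
    Both rise as fatigue-driven amplitude growth accumulates; the choice is
    exposed because the field uses the term loosely.
    """
    if definition == "total":
        return integrate.trapezoid(spec.power, spec.freqs, axis=0)
    if definition == "median_psd":
        return np.median(spec.power, axis=0)
    raise ValueError(f"unknown median-power definition {definition!r}")


def spectral_trend(
    values: np.ndarray, times: np.ndarray | None = None, k: int = 3
) -> TrendResult:
    """Slope and final/initial ratio of a per-window trace.

    The slope is the least-squares line through (time, value); the ratio is
    mean(last k windows) / mean(first k windows). NaN windows (e.g. dropped
    zero-power windows) are excluded and counted.
    """
    values = np.asarray(values, dtype=float).ravel()
    if times is None:
        times = np.arange(values.size, dtype=float)
    else:
        times = np.asarray(times, dtype=float).ravel()
    keep = np.isfinite(values)
    n_dropped = int((~keep).sum())
    values, times = values[keep], times[keep]
    if values.size < 2:
        raise ValueError("spectral_trend needs at least 2 finite windows")
    k = int(min(max(k, 1), values.size))
    slope = float(np.polyfit(times, values, 1)[0])
    first = float(np.mean(values[:k]))
    last = float(np.mean(values[-k:]))
    ratio = last / first if first != 0 else np.nan
    return TrendResult(slope, ratio, values.size, n_dropped)


# ---------------------------------------------------------------------------
# Measure 4: accumulated squared activation


def fatigue_accumulation(
    acts: ActivationSet | np.ndarray, times: np.ndarray | None = None
) -> float:
    """FAT = sum over channels of the time integral of sigma^2.

    Trapezoidal integration; additive over channels and monotone
    non-decreasing in the integration horizon.
    """
    if isinstance(acts, ActivationSet):
        data, t = acts.data, acts.times
    else:
        data = np.atleast_2d(np.asarray(acts, dtype=float))
        if times is None:
            raise ValueError("times required when passing a bare array")
        t = np.asarray(times, dtype=float).ravel()
    if data.shape[1] != t.size:
        raise ValueError("activation traces and time base are misaligned")
    if data.shape[1] < 2:
        return 0.0
    return float(integrate.trapezoid(np.sum(data**2, axis=0), t))
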