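"""Band powers and the two QEEG trend statistics, RA and ADR.

RA (relative alpha percentage) is the alpha-band power expressed as a
percentage of the total power in the 1-20 Hz band; ADR (alpha-delta ratio)
is the ratio of alpha-band to delta-band power. Both are computed per
bipolar channel from a Welch power spectral density over a short epoch
ending at each protocol time point.

Band edges follow standard clinical definitions (delta 1-4, theta 4-8,
alpha 8-13, beta 13-20 Hz); the RA denominator band is 1-20 Hz. The PSD
estimator is Welch with 2-s Hann windows at 50% overlap over a 10-s epoch,
after zero-phase 4th-order band-pass filtering at 1.0-35 Hz (the analog
filter corners of the monitoring setup).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import BIPOLAR_CHANNELS, BipolarChannel, bipolar_derive
from .recording import EEGRecording

__all__ = [
    "BandDefinition", "BANDS", "SpectralEstimate", "QEEGValues",
    "band_power", "compute_ra", "compute_adr",
    "welch_estimate", "bandpass", "epoch_qeeg",
    "TIMEPOINT_OFFSETS", "DEFAULT_EPOCH_LENGTH",
]

#: Offsets of the post-clamp time points from the clamp event (seconds).
TIMEPOINT_OFFSETS: dict[str, float] = {"T1": 30.0, "T2": 60.0, "T3": 120.0}

DEFAULT_EPOCH_LENGTH = 10.0
_WELCH_WINDOW = 2.0  # seconds, Hann, 50% overlap


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high <= 35:
            raise ValueError(
                f"band {self.name}: need 0 < low < high <= 35 Hz, "
                f"got [{self.low}, {self.high}]"
            )


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 20.0),
    "total_1_20": BandDefinition("total_1_20", 1.0, 20.0),
}


@dataclass
class SpectralEstimate:
    """A one-sided PSD for a single bipolar channel over one epoch."""

    frequencies: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray          # uV^2/Hz, non-negative
    epoch_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequencies.shape != self.psd.shape:
            raise ValueError("frequencies and psd must have the same shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")


@dataclass
class QEEGValues:
    """RA and ADR for one bipolar channel over one epoch."""

    channel: BipolarChannel
    side: str
    ra: float   # percent, 0..100
    adr: float  # unitless ratio, > 0
    epoch_window: tuple[float, float]


def band_power(est: SpectralEstimate, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over ``[band.low, band.high]`` (uV^2).

    Band edges falling between grid points are handled by linear
    interpolation of the PSD, which makes disjoint bands tile exactly:
    the powers of delta/theta/alpha/beta sum to the 1-20 Hz total.
    """
    f, p = est.frequencies, est.psd
    if band.low < f[0] or band.high > f[-1]:
        raise ValueError(
            f"band [{band.low}, {band.high}] Hz outside PSD grid "
            f"[{f[0]:g}, {f[-1]:g}] Hz"
        )
    inside = (f > band.low) & (f < band.high)
    grid = np.concatenate(([band.low], f[inside], [band.high]))
    vals = np.concatenate(
        ([np.interp(band.low, f, p)], p[inside], [np.interp(band.high, f, p)])
    )
    return float(np.trapezoid(vals, grid))


def compute_ra(est: SpectralEstimate) -> float:
    """Relative alpha percentage: 100 * P(alpha) / P(1-20 Hz)."""
    total = band_power(est, BANDS["total_1_20"])
    if total <= 0:
        raise ValueError("degenerate epoch: total 1-20 Hz power is zero")
    return 100.0 * band_power(est, BANDS["alpha"]) / total


def compute_adr(est: SpectralEstimate) -> float:
    """Alpha-delta ratio: P(alpha) / P(delta)."""
    delta = band_power(est, BANDS["delta"])
    if delta <= 0:
        raise ValueError("degenerate epoch: delta band power is zero")
    return band_power(est, BANDS["alpha"]) / delta


def bandpass(x: np.ndarray, fs: float, low: float = 1.0, high: float = 35.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def welch_estimate(x: np.ndarray, fs: float,
                   window_sec: float = _WELCH_WINDOW,
                   epoch_window: tuple[float, float] = (0.0, 0.0)) -> SpectralEstimate:
    """Welch PSD with Hann windows at 50% overlap."""
    nperseg = int(round(window_sec * fs))
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2)
    return SpectralEstimate(freqs, psd, epoch_window)


def epoch_qeeg(rec: EEGRecording, side: str, time_point: str,
               epoch_length: float = DEFAULT_EPOCH_LENGTH) -> list[QEEGValues]:
    """RA and ADR for the eight ipsilateral bipolar channels at a time point.

    The epoch is the ``epoch_length``-second window *ending* at the time
    point: at the clamp instant for the baseline ``TB``, and at
    clamp + 30/60/120 s for ``T1``/``T2``/``T3``. Each bipolar series is
    band-pass filtered at 1.0-35 Hz before Welch estimation.
    """
    clamp = rec.event_time("clamp")
    if time_point == "TB":
        end = clamp
    elif time_point in TIMEPOINT_OFFSETS:
        end = clamp + TIMEPOINT_OFFSETS[time_point]
    else:
        raise ValueError(f"unknown time point {time_point!r}")
    start = end - epoch_length
    if start < 0 or end > rec.duration + 1e-9:
        raise ValueError(
            f"epoch [{start:g}, {end:g}] s for {time_point} extends outside "
            f"the recording (duration {rec.duration:g} s)"
        )
    fs = rec.sampling_rate
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    # filter a padded slice rather than the whole record (same result at the
    # epoch interior, far cheaper on long recordings)
    pad = int(round(4 * fs))
    j0, j1 = max(0, i0 - pad), min(rec.n_samples, i1 + pad)

    out = []
    for ch in BIPOLAR_CHANNELS:
        series = bandpass(bipolar_derive(rec, ch, side)[j0:j1], fs)
        est = welch_estimate(series[i0 - j0 : i1 - j0], fs,
                             epoch_window=(start, end))
        out.append(QEEGValues(ch, side, compute_ra(est), compute_adr(est),
                              (start, end)))
    return out
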