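"""Band-limited Hilbert envelopes, trial averaging and TFD spectrograms.

A continuous network time-course (600 Hz) is filtered into a set of
partially overlapping frequency bands; the amplitude envelope of each band
is the magnitude of its analytic signal.  Envelopes are epoched on stimulus
onsets, averaged within each relevance condition over the first 900
post-stimulus samples (1500 ms), and expressed as absolute change from the
resting baseline (the mean envelope over the 30 s rest windows), yielding a
time-frequency difference (TFD) spectrogram.  The beta series entering the
group statistics averages three beta sub-bands and is downsampled into 18
bins of 50 samples (an 83 ms averaging kernel).

Filtering and the Hilbert transform are applied to the whole recording
before epoching, so filter transients live at the recording edges rather
than at every trial boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .task import EventSchedule
from .weibull import FS, N_SAMPLES

__all__ = [
    "DEFAULT_BANDS",
    "BETA_BANDS",
    "GAMMA_BANDS",
    "bandpass",
    "hilbert_envelope",
    "band_envelopes",
    "trial_average",
    "baseline_subtract",
    "TFDSpectrogram",
    "bin_beta",
    "BinnedBetaSeries",
    "N_BINS",
    "BIN_WIDTH",
]

#: The 15 printed analysis bands, 1-70 Hz. The band count is configurable
#: everywhere a band set is accepted.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1, 4), (2, 6), (4, 8), (6, 10), (8, 13), (10, 15), (13, 20), (15, 25),
    (20, 30), (25, 35), (30, 40), (45, 50), (50, 60), (55, 65), (60, 70),
)

#: Beta sub-bands averaged for the binned group analysis.
BETA_BANDS: tuple[tuple[float, float], ...] = ((13, 20), (15, 25), (20, 30))

#: Printed gamma bands used for beta-gamma coupling.
GAMMA_BANDS: tuple[tuple[float, float], ...] = (
    (25, 35), (30, 40), (45, 50), (50, 60), (55, 65), (60, 70),
)

N_BINS = 18
BIN_WIDTH = 50


def _check_band(band, fs: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not (0.0 < low < high):
        raise ValueError(f"invalid band {band}")
    if high >= fs / 2.0:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)")
    return low, high


def bandpass(ts: np.ndarray, band: tuple[float, float], fs: float = FS,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, 4th order/pass)."""
    low, high = _check_band(band, fs)
    x = np.asarray(ts, dtype=float)
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def hilbert_envelope(ts: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal."""
    x = np.asarray(ts, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.abs(sps.hilbert(x))


def band_envelopes(ts: np.ndarray, bands=DEFAULT_BANDS, fs: float = FS) -> np.ndarray:
    """band x time matrix of Hilbert envelopes of the band-passed series."""
    return np.stack([hilbert_envelope(bandpass(ts, b, fs)) for b in bands])


def _epoch_starts(schedule: EventSchedule, condition: str, fs: float,
                  n_times: int, n_samples: int) -> np.ndarray:
    onsets = schedule.onsets_ms(condition)
    if onsets.size == 0:
        raise ValueError(f"no epochs for condition {condition!r}")
    starts = np.round(onsets / 1000.0 * fs).astype(int)
    if starts.min() < 0 or (starts.max() + n_samples) > n_times:
        raise ValueError("epoch extends outside the recording")
    return starts


def trial_average(env: np.ndarray, schedule: EventSchedule, condition: str,
                  fs: float = FS, n_samples: int = N_SAMPLES) -> np.ndarray:
    """Mean band x 900 epoch over one condition's non-target trials.

    Relevant trials pool both stimulus types, as do irrelevant trials, so
    the conditions differ only in task relevance.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    starts = _epoch_starts(schedule, condition, fs, env.shape[1], n_samples)
    acc = np.zeros((env.shape[0], n_samples))
    for k in starts:
        acc += env[:, k:k + n_samples]
    return acc / starts.size


@dataclass(frozen=True)
class TFDSpectrogram:
    """Trial-averaged envelope change from resting baseline, band x time."""

    values: np.ndarray  # (n_bands, n_samples)
    baseline_per_band: np.ndarray  # (n_bands,)
    bands: tuple[tuple[float, float], ...]
    condition: str

    def raw_average(self) -> np.ndarray:
        """Reconstruct the raw trial-averaged envelope exactly."""
        return self.values + self.baseline_per_band[:, None]


def baseline_subtract(avg: np.ndarray, env: np.ndarray,
                      rest_windows, bands=DEFAULT_BANDS,
                      condition: str = "", fs: float = FS) -> TFDSpectrogram:
    """Subtract each band's mean rest-period envelope from the average.

    All rest windows of the session are pooled into one mean per band.
    """
    rest_windows = list(rest_windows)
    if not rest_windows:
        raise ValueError("rest windows must be nonempty")
    env = np.atleast_2d(np.asarray(env, dtype=float))
    avg = np.atleast_2d(np.asarray(avg, dtype=float))
    idx = []
    for start_ms, end_ms in rest_windows:
        k0 = int(np.round(start_ms / 1000.0 * fs))
        k1 = int(np.round(end_ms / 1000.0 * fs))
        if k0 < 0 or k1 > env.shape[1] or k1 <= k0:
            raise ValueError("rest window outside the recording")
        idx.append(np.arange(k0, k1))
    idx = np.concatenate(idx)
    baseline = env[:, idx].mean(axis=1)
    return TFDSpectrogram(avg - baseline[:, None], baseline, tuple(bands), condition)


@dataclass(frozen=True)
class BinnedBetaSeries:
    """18-bin beta series for one subject/network/condition."""

    bins: np.ndarray  # (18,)
    bin_width_samples: int = BIN_WIDTH
    subject: str = ""
    network: str = ""
    condition: str = ""


def bin_series(series: np.ndarray, n_bins: int = N_BINS,
               bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Averaging-kernel downsample: mean within consecutive 50-sample bins."""
    x = np.asarray(series, dtype=float)
    if x.size != n_bins * bin_width:
        raise ValueError(f"expected {n_bins * bin_width} samples, got {x.size}")
    return x.reshape(n_bins, bin_width).mean(axis=1)


def bin_beta(tfd: TFDSpectrogram, beta_bands=BETA_BANDS,
             subject: str = "", network: str = "") -> BinnedBetaSeries:
    """Average the three beta-band rows, then bin into 18 x 50 samples."""
    rows = []
    band_list = [tuple(map(float, b)) for b in tfd.bands]
    for b in beta_bands:
        b = tuple(map(float, b))
        if b not in band_list:
            raise ValueError(f"beta band {b} missing from the spectrogram")
        rows.append(tfd.values[band_list.index(b)])
    beta = np.mean(rows, axis=0)
    if beta.size != N_BINS * BIN_WIDTH:
        raise ValueError(
            f"beta series must have {N_BINS * BIN_WIDTH} samples, got {beta.size}"
        )
    return BinnedBetaSeries(bin_series(beta), BIN_WIDTH, subject, network,
                            tfd.condition)
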