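"""Time-domain preprocessing and windowed-Fourier time-frequency analysis.

Single-trial EEG epochs (trial x channel x sample) are band-pass filtered,
artifact-rejected by an amplitude threshold, baseline corrected over the
prestimulus interval, averaged into per-energy evoked waveforms, and
decomposed into spectrograms P(t, f) = |F(t, f)|**2 with a short-time Fourier
transform using a fixed 200 ms Hann taper.

Numerical conventions
---------------------
* Band-pass filter: 4th-order Butterworth, applied forward-backward
  (zero-phase, effective 8th order); the band edges are -3 dB points of the
  single pass.
* Spectrogram grid: times every ``t_step_ms`` across the full epoch,
  frequencies on an integer-Hz grid.  A 200 ms taper has a natural resolution
  of 5 Hz; 1 Hz bin spacing is obtained by zero-padding each tapered segment
  to one second.  Epoch edges are reflect-padded by half a window so the time
  grid spans the whole epoch; estimates whose window extends beyond the
  recorded data are flagged in ``Spectrogram.edge_flag``.
* No baseline correction is applied to spectrograms: prestimulus and
  poststimulus power must remain on a common scale for the regression
  analyses downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: default artifact-rejection threshold (microvolt)
REJECT_THRESHOLD_UV = 100.0
#: default N2/P2 search window (ms after stimulus onset)
PEAK_WINDOW_MS = (150.0, 500.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial labels.

    Attributes
    ----------
    data : array, shape (n_trials, n_channels, n_samples)
        Amplitude in microvolt.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in ms relative to stimulus onset (<= 0).
    ch_names : list of str
    energies : array of int, per-trial stimulus-energy index (0..n_energies-1)
    ratings : array of float, per-trial perceived-intensity rating (0..10)
    subject : identifier
    trial_ids : array of int, original trial indices (survives rejection)
    """

    data: np.ndarray
    fs: float
    t0: float
    ch_names: list[str]
    energies: np.ndarray
    ratings: np.ndarray
    subject: str = "S0"
    trial_ids: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.energies = np.asarray(self.energies)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n = self.data.shape[0]
        if len(self.energies) != n or len(self.ratings) != n:
            raise ValueError("per-trial labels must match n_trials")
        if not np.all(np.isfinite(self.ratings)):
            raise ValueError("ratings must be finite")
        n_samp = self.data.shape[2]
        if not (self.t0 <= 0.0 < self.t0 + n_samp / self.fs * 1000.0):
            raise ValueError("epoch must span stimulus onset (t = 0)")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + np.arange(self.data.shape[2]) * 1000.0 / self.fs

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)


@dataclass
class Spectrogram:
    """Single-trial power spectrogram on a regular time-frequency grid.

    ``power[trial, f, t]`` is the squared modulus of the windowed Fourier
    coefficient, in microvolt**2.
    """

    power: np.ndarray                      # (n_trials, n_freqs, n_times)
    freqs: np.ndarray                      # Hz
    times: np.ndarray                      # ms
    window_ms: float
    channel: str = ""
    complex_coeffs: np.ndarray | None = None
    edge_flag: np.ndarray | None = None    # (n_times,) True where window padded

    def __post_init__(self):
        if np.any(self.power < -1e-12):
            raise ValueError("power must be nonnegative")


@dataclass
class PeakMeasures:
    """N2 (most negative) and P2 (most positive) deflections in a window."""

    n2_latency: float
    n2_amplitude: float
    p2_latency: float
    p2_amplitude: float
    window: tuple[float, float]
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(data: np.ndarray, fs: float, low: float = 1.0,
                    high: float = 100.0, order: int = 4,
                    axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis``.

    ``order`` is the single-pass filter order; the forward-backward
    application doubles the effective order and cancels phase delay.
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=axis)


def reject_artifacts(epochs: EpochSet,
                     threshold: float = REJECT_THRESHOLD_UV) -> EpochSet:
    """Drop trials with any sample exceeding ``+-threshold`` microvolt.

    Idempotent; raises if no trial survives.  Rejections are reported through
    the module logger.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.any(np.abs(epochs.data) > threshold, axis=(1, 2))
    if bad.all():
        raise ValueError("no trials survive artifact rejection "
                         f"at +-{threshold} uV")
    if bad.any():
        logger.info("rejected %d/%d trials (+-%g uV): original ids %s",
                    bad.sum(), epochs.n_trials, threshold,
                    epochs.trial_ids[bad].tolist())
    keep = ~bad
    return replace(epochs, data=epochs.data[keep],
                   energies=epochs.energies[keep],
                   ratings=epochs.ratings[keep],
                   trial_ids=epochs.trial_ids[keep])


def baseline_correct(epochs: EpochSet,
                     interval: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the mean over ``interval`` (ms) per trial and channel.

    Defaults to the full prestimulus interval (t0..0).
    """
    if interval is None:
        interval = (epochs.t0, 0.0)
    t = epochs.times
    mask = (t >= interval[0]) & (t <= interval[1])
    if not mask.any():
        raise ValueError(f"empty baseline interval {interval}")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


# ---------------------------------------------------------------------------
# time-frequency decomposition
# ---------------------------------------------------------------------------

def _hann(n: int) -> np.ndarray:
    return signal.get_window("hann", n, fftbins=False)


def wft_spectrogram(epochs: EpochSet, channel: str | int = 0,
                    window_ms: float = 200.0, t_step_ms: float = 1.0,
                    f_max: float = 100.0, f_step: float = 1.0,
                    keep_complex: bool = False,
                    taper: str = "hann") -> Spectrogram:
    """Windowed Fourier transform spectrogram of one channel.

    For every requested time t the epoch segment of length ``window_ms``
    centred on t is Hann-tapered, zero-padded to one second (1 Hz bins) and
    Fourier transformed; ``power = |F(t, f)|**2``.  The time grid covers the
    full epoch in steps of ``t_step_ms``; frequencies run 1..``f_max`` Hz in
    steps of ``f_step`` (integer Hz).  The epoch is reflect-padded by half a
    window at each edge; padded estimates are flagged, not dropped.
    """
    ch = channel if isinstance(channel, int) else epochs.channel_index(channel)
    fs = epochs.fs
    nwin = int(round(window_ms * fs / 1000.0))
    step = int(round(t_step_ms * fs / 1000.0))
    if step < 1 or nwin < 2:
        raise ValueError("window/step too small for sampling rate")
    nfft = int(round(fs))  # zero-pad to 1 s -> 1 Hz bin spacing
    if nfft < nwin:
        raise ValueError("window longer than 1 s not supported on a 1 Hz grid")
    freqs = np.arange(f_step, f_max + 0.5 * f_step, f_step)
    bins = np.round(freqs * nfft / fs).astype(int)
    if bins[-1] > nfft // 2:
        raise ValueError("f_max beyond Nyquist")

    x = epochs.data[:, ch, :]                      # (n_trials, n_samples)
    n_samp = x.shape[1]
    half = nwin // 2
    xp = np.pad(x, ((0, 0), (half, half)), mode="reflect")
    centers = np.arange(0, n_samp, step)
    # sliding windows: (n_trials, n_times, nwin)
    idx = centers[:, None] + np.arange(nwin)[None, :]
    win = signal.get_window(taper, nwin, fftbins=False)
    seg = xp[:, idx] * win[None, None, :]
    F = np.fft.rfft(seg, n=nfft, axis=-1)[:, :, bins]   # (trials, times, freqs)
    F = np.transpose(F, (0, 2, 1))                      # (trials, freqs, times)
    times = epochs.t0 + centers * 1000.0 / fs
    edge = (centers < half) | (centers > n_samp - 1 - (nwin - half - 1))
    return Spectrogram(power=np.abs(F) ** 2, freqs=freqs, times=times,
                       window_ms=window_ms,
                       channel=str(epochs.ch_names[ch]),
                       complex_coeffs=F if keep_complex else None,
                       edge_flag=edge)


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------

def average_erp(epochs: EpochSet) -> dict[int, np.ndarray]:
    """Per-energy mean waveform, ``{energy: (n_channels, n_samples)}``."""
    out: dict[int, np.ndarray] = {}
    for e in np.unique(epochs.energies):
        m = epochs.energies == e
        if not m.any():
            raise ValueError(f"empty energy group {e}")
        out[int(e)] = epochs.data[m].mean(axis=0)
        logger.debug("energy %s: averaged %d trials", e, m.sum())
    return out


def measure_peaks(waveform: np.ndarray, times: np.ndarray,
                  window: tuple[float, float] = PEAK_WINDOW_MS) -> PeakMeasures:
    """Most negative (N2) and most positive (P2) deflections within ``window``.

    Ties are broken toward the earlier latency (first occurrence).  If both
    extrema sit on the window edges (monotone waveform) the result is flagged
    low-confidence but still returned.
    """
    waveform = np.asarray(waveform, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("waveform does not cover the search window")
    t_w = times[mask]
    w = waveform[mask]
    i_n2 = int(np.argmin(w))
    i_p2 = int(np.argmax(w))
    edge = {0, len(w) - 1}
    low_conf = i_n2 in edge and i_p2 in edge
    return PeakMeasures(n2_latency=float(t_w[i_n2]), n2_amplitude=float(w[i_n2]),
                        p2_latency=float(t_w[i_p2]), p2_amplitude=float(w[i_p2]),
                        window=window, low_confidence=low_conf)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str) -> None:
    """Write an :class:`EpochSet` to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("energies", data=epochs.energies)
        f.create_dataset("ratings", data=epochs.ratings)
        f.create_dataset("trial_ids", data=epochs.trial_ids)
        f.attrs["fs"] = epochs.fs
        f.attrs["t0"] = epochs.t0
        f.attrs["subject"] = epochs.subject
        f.attrs["ch_names"] = ",".join(epochs.ch_names)


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(data=f["data"][()], fs=float(f.attrs["fs"]),
                        t0=float(f.attrs["t0"]),
                        ch_names=str(f.attrs["ch_names"]).split(","),
                        energies=f["energies"][()], ratings=f["ratings"][()],
                        subject=str(f.attrs["subject"]),
                        trial_ids=f["trial_ids"][()])
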