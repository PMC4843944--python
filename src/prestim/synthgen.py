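"""Synthetic EEG and BOLD data with planted prestimulus brain-state effects.

The generators emulate the statistical structure the downstream analyses
assume, with a stored ground truth for recovery tests:

EEG (per subject)
    Epochs of -500..1000 ms at 1000 Hz containing 1/f**chi Gaussian
    background noise, Hann-tapered alpha (8-15 Hz) and gamma (74-87 Hz)
    oscillatory bursts confined to a prestimulus window with trial-varying
    (log-normal) amplitude, and an energy-scaled N2-P2 evoked complex
    (negative peak ~200 ms, positive peak ~350 ms).  Perceived-intensity
    ratings are a linear function of stimulus energy plus standardized
    contributions of the *latent* prestimulus band powers plus Gaussian
    noise, clipped to the 0..10 rating scale.

BOLD (per subject)
    A small voxel grid scanned at TR = 1.5 s: white noise + slow drift +
    event-locked double-gamma responses scaled with stimulus energy, plus a
    low-pass-filtered Gaussian "resting state" fluctuation added to a
    positively and a negatively predictive voxel mask.  The fluctuation
    sampled at each trial onset enters the rating model with positive
    (pos_mask) or negative (neg_mask) sign.

The rating models use the generator's latent amplitudes, never re-estimated
powers, so recovery tests measure the analysis pipeline rather than the
generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .tf import EpochSet

# Per-energy rating baselines and evoked-peak magnitudes follow the graded
# psychophysics and vertex-potential amplitudes typical of four-level
# radiant-heat stimulation of the hand dorsum.
EEG_RATING_BASE = (3.8, 4.9, 6.6, 7.7)          # VAS units, E1..E4
BOLD_RATING_BASE = (2.9, 3.8, 5.7, 6.9)
N2_AMP_UV = (4.3, 10.4, 22.3, 28.1)             # magnitudes, E1..E4
P2_AMP_UV = (3.4, 8.5, 18.0, 23.7)


@dataclass
class EEGSimParams:
    """Parameters of the synthetic EEG experiment (one subject per call)."""

    n_trials_per_energy: int = 10
    n_energies: int = 4
    fs: float = 1000.0
    epoch_window: tuple[float, float] = (-500.0, 1000.0)   # ms
    alpha_band: tuple[float, float] = (8.0, 15.0)          # Hz
    gamma_band: tuple[float, float] = (74.0, 87.0)
    burst_window: tuple[float, float] = (-300.0, 0.0)      # ms, Hann envelope
    alpha_amp_uv: float = 8.0        # median burst amplitude, microvolt
    gamma_amp_uv: float = 3.0
    amp_log_sd: float = 0.5          # log-normal sd of burst amplitudes
    background_rms_uv: float = 10.0  # 1/f background, broadband rms
    chi: float = 1.0                 # 1/f**chi spectral exponent
    beta_alpha: float = -0.5         # standardized rating-modulation coeffs
    beta_gamma: float = -0.5
    rating_base: tuple[float, ...] = EEG_RATING_BASE
    noise_sd: float = 0.8            # rating noise, VAS units
    snr_evoked: float = 1.0          # scales the N2-P2 complex
    n2_latency_ms: float = 200.0
    p2_latency_ms: float = 350.0
    evoked_mod_alpha: float = 0.0    # evoked-amplitude modulation by z(power)
    evoked_mod_gamma: float = 0.0
    redundant_bands: bool = False    # gamma latent := alpha latent
    n_channels: int = 2
    channel_names: tuple[str, ...] = ("C4", "Cz")
    copy_gain: float = 0.6           # attenuation of non-primary channels
    seed: int | None = None

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_energies < 1:
            raise ValueError("need at least one energy level")
        if self.n_trials_per_energy < 2:
            raise ValueError("need >=2 trials per energy")
        if self.alpha_band[1] >= self.gamma_band[0]:
            raise ValueError("alpha and gamma bands must not overlap")
        if self.fs <= 2 * self.gamma_band[1]:
            raise ValueError("fs must exceed twice the upper gamma edge")
        if not (self.epoch_window[0] <= 0.0 < self.epoch_window[1]):
            raise ValueError("epoch window must span stimulus onset")


@dataclass
class GroundTruth:
    """Latent quantities planted by a generator, for recovery oracles."""

    alpha_power: np.ndarray | None = None    # per-trial latent burst power
    gamma_power: np.ndarray | None = None
    beta_alpha: float | None = None
    beta_gamma: float | None = None
    n2_latency_ms: float | None = None
    p2_latency_ms: float | None = None
    n2_amp_by_energy: np.ndarray | None = None
    p2_amp_by_energy: np.ndarray | None = None
    # BOLD
    pos_mask: np.ndarray | None = None
    neg_mask: np.ndarray | None = None
    effect_size_pos: float | None = None
    effect_size_neg: float | None = None
    u_pos: np.ndarray | None = None          # latent slow fluctuation series
    u_neg: np.ndarray | None = None
    pos_onset: np.ndarray | None = None      # latent values at trial onsets
    neg_onset: np.ndarray | None = None
    onset_volumes: np.ndarray | None = None


def _zscore_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Sample (ddof=1) z-score within each group label."""
    out = np.empty_like(values, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        v = values[m]
        out[m] = (v - v.mean()) / v.std(ddof=1)
    return out


def _one_over_f_noise(rng: np.random.Generator, n_trials: int, n_samples: int,
                      fs: float, chi: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f**chi amplitude spectrum, unit-free shaping."""
    white = rng.standard_normal((n_trials, n_samples))
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = 1.0 / np.maximum(f, 1.0) ** (chi / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(F * scale, n=n_samples, axis=-1)
    x *= rms / np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x


def _gauss_bump(t_ms: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def generate_eeg_dataset(params: EEGSimParams,
                         subject: str = "S0") -> tuple[EpochSet, GroundTruth]:
    """Generate one subject's epoched EEG and its ground truth.

    Identical ``params.seed`` gives bitwise-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_e = params.n_energies
    n_per = params.n_trials_per_energy
    n_trials = n_e * n_per
    fs = params.fs
    t = np.arange(params.epoch_window[0], params.epoch_window[1],
                  1000.0 / fs)                                # ms
    n_samp = t.size
    t_s = t / 1000.0

    energies = np.repeat(np.arange(n_e), n_per)
    rng.shuffle(energies)                                     # pseudorandom order

    # latent burst amplitudes (log-normal around the configured median)
    a_alpha = params.alpha_amp_uv * np.exp(
        params.amp_log_sd * rng.standard_normal(n_trials))
    if params.redundant_bands:
        a_gamma = params.gamma_amp_uv * (a_alpha / params.alpha_amp_uv)
    else:
        a_gamma = params.gamma_amp_uv * np.exp(
            params.amp_log_sd * rng.standard_normal(n_trials))
    alpha_power = a_alpha ** 2
    gamma_power = a_gamma ** 2

    # Hann envelope over the prestimulus burst window
    w0, w1 = params.burst_window
    env = np.zeros(n_samp)
    m = (t >= w0) & (t <= w1)
    env[m] = np.hanning(m.sum())

    f_alpha = rng.uniform(*params.alpha_band, size=n_trials)
    f_gamma = rng.uniform(*params.gamma_band, size=n_trials)
    ph_a = rng.uniform(0, 2 * np.pi, size=n_trials)
    ph_g = rng.uniform(0, 2 * np.pi, size=n_trials)
    bursts = (a_alpha[:, None] * env * np.cos(2 * np.pi * f_alpha[:, None] * t_s + ph_a[:, None])
              + a_gamma[:, None] * env * np.cos(2 * np.pi * f_gamma[:, None] * t_s + ph_g[:, None]))

    # evoked N2-P2 complex, scaled by energy and (optionally) by latent power
    z_a = _zscore_within(alpha_power, energies)
    z_g = _zscore_within(gamma_power, energies)
    n2_amp = np.asarray(N2_AMP_UV[:n_e]) * params.snr_evoked
    p2_amp = np.asarray(P2_AMP_UV[:n_e]) * params.snr_evoked
    gain = 1.0 + params.evoked_mod_alpha * z_a + params.evoked_mod_gamma * z_g
    shape = (-_gauss_bump(t, params.n2_latency_ms, 30.0)[None, :]
             * (n2_amp[energies] * gain)[:, None]
             + _gauss_bump(t, params.p2_latency_ms, 60.0)[None, :]
             * (p2_amp[energies] * gain)[:, None])

    primary = (_one_over_f_noise(rng, n_trials, n_samp, fs, params.chi,
                                 params.background_rms_uv)
               + bursts + shape)
    data = np.empty((n_trials, params.n_channels, n_samp))
    data[:, 0, :] = primary
    for c in range(1, params.n_channels):
        data[:, c, :] = (params.copy_gain * primary
                         + _one_over_f_noise(rng, n_trials, n_samp, fs,
                                             params.chi,
                                             0.8 * params.background_rms_uv))

    base = np.asarray(params.rating_base[:n_e], dtype=float)
    ratings = (base[energies]
               + params.beta_alpha * z_a + params.beta_gamma * z_g
               + params.noise_sd * rng.standard_normal(n_trials))
    ratings = np.clip(ratings, 0.0, 10.0)

    epochs = EpochSet(data=data, fs=fs, t0=params.epoch_window[0],
                      ch_names=list(params.channel_names[:params.n_channels]),
                      energies=energies, ratings=ratings, subject=subject)
    truth = GroundTruth(alpha_power=alpha_power, gamma_power=gamma_power,
                        beta_alpha=params.beta_alpha,
                        beta_gamma=params.beta_gamma,
                        n2_latency_ms=params.n2_latency_ms,
                        p2_latency_ms=params.p2_latency_ms,
                        n2_amp_by_energy=-n2_amp, p2_amp_by_energy=p2_amp)
    return epochs, truth


def generate_eeg_cohort(params: EEGSimParams, n_subjects: int,
                        seed: int | None = None
                        ) -> tuple[list[EpochSet], list[GroundTruth]]:
    """Generate a cohort with independent per-subject substreams of ``seed``."""
    from dataclasses import replace as _replace
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    subs, truths = [], []
    for i, child in enumerate(ss.spawn(n_subjects)):
        p = _replace(params, seed=child)
        ep, gt = generate_eeg_dataset(p, subject=f"S{i:02d}")
        subs.append(ep)
        truths.append(gt)
    return subs, truths


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

@dataclass
class BOLDSimParams:
    """Parameters of the synthetic event-related fMRI experiment."""

    grid_shape: tuple[int, int, int] = (12, 12, 8)
    tr: float = 1.5                                  # s
    n_trials_per_energy: int = 10
    n_energies: int = 4
    isi_range: tuple[float, float] = (27.0, 33.0)    # s
    pos_mask: np.ndarray | None = None               # boolean voxel masks
    neg_mask: np.ndarray | None = None
    effect_size_pos: float = 0.5    # standardized onset-signal -> rating coeff
    effect_size_neg: float = 0.5    # enters the rating model with minus sign
    fluct_amp: float = 1.0          # slow-fluctuation amplitude (signal units)
    fluct_cutoff_hz: float = 0.05   # low-pass cutoff of the fluctuation
    noise_sd: float = 1.0           # white voxel noise
    drift_amp: float = 2.0          # slow scanner drift amplitude
    evoked_amp: float = 2.0         # peak evoked response at highest energy
    rating_base: tuple[float, ...] = BOLD_RATING_BASE
    rating_noise_sd: float = 0.8
    align_onsets: bool = True       # snap onsets to the TR grid
    seed: int | None = None

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] <= 0:
            raise ValueError("invalid ISI range")
        if self.pos_mask is not None and self.neg_mask is not None:
            if np.any(self.pos_mask & self.neg_mask):
                raise ValueError("pos_mask and neg_mask must be disjoint")


@dataclass
class BOLDDataset:
    """4D voxel time series with trial metadata."""

    series: np.ndarray               # (x, y, z, n_volumes)
    tr: float
    onsets: np.ndarray               # s, per trial
    energies: np.ndarray
    ratings: np.ndarray
    subject: str = "S0"

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        dur = self.series.shape[-1] * self.tr
        if np.any(self.onsets < 0) or np.any(self.onsets >= dur):
            raise ValueError("onsets must fall within the scan")

    @property
    def n_volumes(self) -> int:
        return self.series.shape[-1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr


def default_masks(grid_shape: tuple[int, int, int]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint cubic voxel masks inside ``grid_shape``."""
    pos = np.zeros(grid_shape, dtype=bool)
    neg = np.zeros(grid_shape, dtype=bool)
    nx, ny, nz = grid_shape
    pos[1:4, 1:4, 1:4] = True
    neg[nx - 4:nx - 1, ny - 4:ny - 1, nz - 4:nz - 1] = True
    return pos, neg


def _slow_fluctuation(rng: np.random.Generator, n_vol: int, tr: float,
                      cutoff_hz: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian process on the volume grid."""
    white = rng.standard_normal(n_vol)
    fs = 1.0 / tr
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    u = signal.sosfiltfilt(sos, white)
    sd = u.std()
    return u / sd if sd > 0 else u


def generate_bold_dataset(params: BOLDSimParams, subject: str = "S0"
                          ) -> tuple[BOLDDataset, GroundTruth]:
    """Generate one subject's 4D BOLD series and its ground truth."""
    from .boldpls import canonical_hrf

    params.validate()
    rng = np.random.default_rng(params.seed)
    pos = params.pos_mask
    neg = params.neg_mask
    if pos is None or neg is None:
        d_pos, d_neg = default_masks(params.grid_shape)
        pos = d_pos if pos is None else pos
        neg = d_neg if neg is None else neg
        if np.any(pos & neg):
            raise ValueError("pos_mask and neg_mask must be disjoint")

    n_e = params.n_energies
    n_trials = n_e * params.n_trials_per_energy
    energies = np.repeat(np.arange(n_e), params.n_trials_per_energy)
    rng.shuffle(energies)

    isi = rng.uniform(*params.isi_range, size=n_trials)
    onsets = 20.0 + np.concatenate([[0.0], np.cumsum(isi[:-1])])
    if params.align_onsets:
        onsets = np.round(onsets / params.tr) * params.tr
    n_vol = int(np.ceil((onsets[-1] + 25.0) / params.tr))
    frame_t = np.arange(n_vol) * params.tr

    # event-locked evoked response, common to all voxels
    hrf = canonical_hrf(params.tr)
    stick = np.zeros(n_vol)
    amp = params.evoked_amp * (energies + 1) / n_e
    vol_idx = np.floor(onsets / params.tr).astype(int)
    np.add.at(stick, vol_idx, amp)
    evoked = np.convolve(stick, hrf)[:n_vol]

    # slow latent fluctuations in the predictive masks
    u_pos = _slow_fluctuation(rng, n_vol, params.tr, params.fluct_cutoff_hz)
    u_neg = _slow_fluctuation(rng, n_vol, params.tr, params.fluct_cutoff_hz)

    n_vox = int(np.prod(params.grid_shape))
    series = params.noise_sd * rng.standard_normal((n_vox, n_vol))
    # slow scanner drift: linear + one slow cosine, random phase per voxel
    drift_ph = rng.uniform(0, 2 * np.pi, size=n_vox)
    lin = np.linspace(-1, 1, n_vol)
    series += params.drift_amp * (0.5 * lin[None, :] + 0.5 * np.cos(
        2 * np.pi * frame_t[None, :] / (frame_t[-1] + params.tr)
        + drift_ph[:, None]))
    series += evoked[None, :]
    series = series.reshape(params.grid_shape + (n_vol,))
    series[pos] += params.fluct_amp * u_pos
    series[neg] += params.fluct_amp * u_neg

    pos_onset = u_pos[vol_idx]
    neg_onset = u_neg[vol_idx]
    base = np.asarray(params.rating_base[:n_e], dtype=float)
    ratings = (base[energies]
               + params.effect_size_pos * _zscore_within(pos_onset, energies)
               - params.effect_size_neg * _zscore_within(neg_onset, energies)
               + params.rating_noise_sd * rng.standard_normal(n_trials))
    ratings = np.clip(ratings, 0.0, 10.0)

    ds = BOLDDataset(series=series, tr=params.tr, onsets=onsets,
                     energies=energies, ratings=ratings, subject=subject)
    truth = GroundTruth(pos_mask=pos, neg_mask=neg,
                        effect_size_pos=params.effect_size_pos,
                        effect_size_neg=params.effect_size_neg,
                        u_pos=u_pos, u_neg=u_neg,
                        pos_onset=pos_onset, neg_onset=neg_onset,
                        onset_volumes=vol_idx)
    return ds, truth


def generate_bold_cohort(params: BOLDSimParams, n_subjects: int,
                         seed: int | None = None
                         ) -> tuple[list[BOLDDataset], list[GroundTruth]]:
    from dataclasses import replace as _replace
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    subs, truths = [], []
    for i, child in enumerate(ss.spawn(n_subjects)):
        p = _replace(params, seed=child)
        ds, gt = generate_bold_dataset(p, subject=f"S{i:02d}")
        subs.append(ds)
        truths.append(gt)
    return subs, truths
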