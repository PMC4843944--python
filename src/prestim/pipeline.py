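"""End-to-end orchestration of the prestimulus EEG/BOLD analyses.

These helpers chain the module-level operations in the order a study would
run them (preprocess -> spectrogram -> within-energy normalization -> PLS ->
group t -> clusters -> permutation), for a cohort of subjects.  Analysis
resolution is configurable: the spectrogram time axis can be decimated and
the frequency axis coarsened; moderate decimation does not change cluster
detection because a 200 ms analysis window already smooths the grid well
below its nominal 1 ms x 1 Hz spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clusterstat, plsmap, predict, stateeffects, tf
from .tf import EpochSet, Spectrogram


@dataclass
class EEGAnalysisConfig:
    """Resolution and statistical settings of the cohort EEG analysis."""

    channel: str | int = 0
    window_ms: float = 200.0
    t_step_ms: float = 5.0       # spectrogram time decimation
    f_step: float = 1.0
    f_max: float = 100.0
    n_components: int = plsmap.N_COMPONENTS
    cluster_alpha: float = clusterstat.CLUSTER_ALPHA
    min_cluster_size: int = clusterstat.MIN_CLUSTER_SIZE
    n_perm: int = clusterstat.N_PERMUTATIONS
    reject_uv: float = tf.REJECT_THRESHOLD_UV
    preprocess: bool = True      # amplitude rejection + baseline correction
    scheme: str = "mask"


@dataclass
class EEGAnalysisResult:
    tmap: clusterstat.TMap
    clusters: list[clusterstat.TFCluster]
    selected: dict[str, list[clusterstat.TFCluster]]
    coef_maps: np.ndarray              # (n_subjects, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    spectrograms: list[Spectrogram] = field(repr=False, default_factory=list)
    epochs: list[EpochSet] = field(repr=False, default_factory=list)
    features: list[np.ndarray] = field(repr=False, default_factory=list)
    ratings: list[np.ndarray] = field(repr=False, default_factory=list)
    energies: list[np.ndarray] = field(repr=False, default_factory=list)


def subject_spectrogram(epochs: EpochSet, cfg: EEGAnalysisConfig
                        ) -> tuple[EpochSet, Spectrogram]:
    """Preprocess one subject's epochs and compute the analysis spectrogram."""
    if cfg.preprocess:
        epochs = tf.reject_artifacts(epochs, cfg.reject_uv)
        epochs = tf.baseline_correct(epochs)
    spec = tf.wft_spectrogram(epochs, channel=cfg.channel,
                              window_ms=cfg.window_ms,
                              t_step_ms=cfg.t_step_ms,
                              f_max=cfg.f_max, f_step=cfg.f_step)
    return epochs, spec


def eeg_cluster_analysis(cohort: list[EpochSet],
                         cfg: EEGAnalysisConfig | None = None,
                         seed=None) -> EEGAnalysisResult:
    """Cohort-level prestimulus spectrogram-vs-rating cluster analysis."""
    cfg = cfg or EEGAnalysisConfig()
    specs, eps, feats, rates, energies, coefs = [], [], [], [], [], []
    freqs = times = None
    for ep in cohort:
        ep, spec = subject_spectrogram(ep, cfg)
        freqs, times = spec.freqs, spec.times
        flat = spec.power.reshape(spec.power.shape[0], -1)
        Z, keep = plsmap.drop_zero_sd_columns(flat, ep.energies)
        if not keep.all():                 # keep grid alignment
            full = np.zeros_like(flat)
            full[:, keep] = Z
            Z = full
        y = plsmap.normalize_within_energy(ep.ratings, ep.energies)
        coef, _ = plsmap.simpls(Z, y, cfg.n_components)
        coefs.append(coef.reshape(spec.power.shape[1:]))
        specs.append(spec)
        eps.append(ep)
        feats.append(Z)
        rates.append(y)
        energies.append(ep.energies)
    coef_maps = np.asarray(coefs)
    tmap = clusterstat.tmap_one_sample(coef_maps)
    clusters = clusterstat.form_clusters(tmap, alpha=cfg.cluster_alpha,
                                         min_size=cfg.min_cluster_size)
    if clusters and cfg.n_perm > 0:
        clusterstat.permutation_pvalues(
            feats, rates, energies, clusters, tmap.t.shape,
            n_perm=cfg.n_perm, n_components=cfg.n_components, seed=seed,
            scheme=cfg.scheme, alpha=cfg.cluster_alpha,
            min_size=cfg.min_cluster_size)
    selected = clusterstat.select_band_clusters(clusters, freqs, times)
    return EEGAnalysisResult(tmap=tmap, clusters=clusters, selected=selected,
                             coef_maps=coef_maps, freqs=freqs, times=times,
                             spectrograms=specs, epochs=eps, features=feats,
                             ratings=rates, energies=energies)


def band_window_mask(freqs: np.ndarray, times: np.ndarray,
                     f_band: tuple[float, float],
                     t_window: tuple[float, float]) -> np.ndarray:
    """Boolean (freq, time) mask for a band x interval rectangle."""
    return ((freqs >= f_band[0]) & (freqs <= f_band[1]))[:, None] \
        & ((times >= t_window[0]) & (times <= t_window[1]))[None, :]


def prestim_feature_sets(spec: Spectrogram, masks: dict[str, np.ndarray],
                         ratings: np.ndarray, energies: np.ndarray
                         ) -> list[predict.FeatureSet]:
    """Per-trial cluster-power feature sets plus their combination.

    ``masks`` maps names (e.g. ``"Pre-ABO"``) to (freq, time) boolean masks;
    labels come from within-energy rating binarization.
    """
    labels, kept = predict.binarize_ratings(ratings, energies)
    single = {name: stateeffects.cluster_power_per_trial(spec, mask)
              for name, mask in masks.items()}
    return predict.make_feature_sets(single, labels, kept)
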