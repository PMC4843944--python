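"""Median-split analysis of prestimulus cluster power.

Trials are scored by the mean spectrogram power inside a named prestimulus
time-frequency cluster (at one electrode), split at the median into low- and
high-power halves, and the per-cell mean ratings, evoked waveforms and N2/P2
peak measures are compared with repeated-measures ANOVA (stimulus energy x
power split, both within subject) plus Tukey HSD post-hocs.

The split is computed within each stimulus-energy stratum so that the
energy x split design stays balanced.  With an odd number of trials in a
stratum the median trial is dropped; ties are resolved by stable sort order,
so repeated runs give identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tf
from ._anova import (AnovaTable, EffectResult, rm_anova_oneway,
                     rm_anova_twoway, tukey_rm, greenhouse_geisser_eps)
from .clusterstat import TFCluster
from .tf import EpochSet, Spectrogram, measure_peaks

from scipy import stats as _stats


def cluster_power_per_trial(spec: Spectrogram,
                            cluster: TFCluster | np.ndarray) -> np.ndarray:
    """Mean spectrogram power over a cluster mask, per trial (microvolt**2)."""
    mask = cluster.mask if isinstance(cluster, TFCluster) else np.asarray(cluster)
    if mask.shape != spec.power.shape[1:]:
        raise ValueError("cluster mask does not match spectrogram grid")
    if not mask.any():
        raise ValueError("empty cluster mask")
    return spec.power[:, mask].mean(axis=1)


def median_split(powers: np.ndarray) -> np.ndarray:
    """Label trials ``0`` (low) / ``1`` (high) by a median split; ``-1`` dropped.

    The bottom floor(n/2) trials of the ascending (stable) sort are low, the
    top floor(n/2) high; with odd n the median trial is dropped.
    """
    powers = np.asarray(powers, dtype=float)
    n = len(powers)
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    order = np.argsort(powers, kind="stable")
    half = n // 2
    labels = np.full(n, -1, dtype=int)
    labels[order[:half]] = 0
    labels[order[n - half:]] = 1
    return labels


def rm_anova(values: np.ndarray, factor_names: tuple[str, ...] = ("A",),
             posthoc: bool = True, alpha: float = 0.05,
             gg_correction: bool = False) -> AnovaTable:
    """Repeated-measures ANOVA on a balanced within-subject cell table.

    ``values`` has shape (n_subjects, k) for one factor or
    (n_subjects, a, b) for two fully crossed within-subject factors.  Tukey
    HSD pairwise comparisons are attached for significant main effects of a
    one-way design.  ``gg_correction`` applies the Greenhouse-Geisser
    sphericity correction to the one-way df (off by default).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        eff = rm_anova_oneway(values)
        if gg_correction:
            eps = greenhouse_geisser_eps(values)
            p = float(_stats.f.sf(eff.F, eps * eff.df1, eps * eff.df2))
            eff = EffectResult(eff.F, eps * eff.df1, eps * eff.df2, p)
        table = AnovaTable(effects={factor_names[0]: eff})
        if posthoc and eff.p < alpha:
            table.posthoc[factor_names[0]] = tukey_rm(values)
        return table
    if values.ndim == 3:
        names = (factor_names + ("A", "B"))[:2]
        res = rm_anova_twoway(values)
        effects = {names[0]: res["A"], names[1]: res["B"],
                   f"{names[0]}x{names[1]}": res["AxB"]}
        table = AnovaTable(effects=effects)
        if posthoc:
            for ax, nm in ((1, names[0]), (2, names[1])):
                if effects[nm].p < alpha:
                    cell_means = values.mean(axis=3 - ax)  # collapse other factor
                    table.posthoc[nm] = tukey_rm(cell_means)
        return table
    raise ValueError("values must be (subjects, k) or (subjects, a, b)")


@dataclass
class SplitReport:
    """Figure-style summary of a prestimulus-power median-split analysis.

    Cell arrays are (n_subjects, n_energies, 2) with split index 0 = low
    power, 1 = high power.
    """

    cluster_label: str
    electrode: str
    ratings: np.ndarray
    n2_amplitude: np.ndarray
    p2_amplitude: np.ndarray
    n2_latency: np.ndarray
    p2_latency: np.ndarray
    erp: np.ndarray                      # (n_sub, n_energies, 2, n_samples)
    erp_times: np.ndarray
    anova: dict[str, AnovaTable] = field(default_factory=dict)


def split_effect_report(cohort_epochs: list[EpochSet],
                        cohort_specs: list[Spectrogram],
                        cluster: TFCluster | np.ndarray,
                        electrode: str | int = 0,
                        cluster_label: str = "",
                        peak_window: tuple[float, float] = tf.PEAK_WINDOW_MS
                        ) -> SplitReport:
    """Assemble the full median-split analysis for a cohort.

    For every subject, trials are split within energy by cluster power; mean
    rating, mean evoked waveform (at ``electrode``) and N2/P2 peak measures
    are computed per (energy, split) cell, then compared with two-way
    repeated-measures ANOVAs (energy x power).
    """
    n_sub = len(cohort_epochs)
    if n_sub != len(cohort_specs):
        raise ValueError("epochs/spectrograms cohort size mismatch")
    energies_all = np.unique(np.concatenate(
        [ep.energies for ep in cohort_epochs]))
    n_e = len(energies_all)
    ep0 = cohort_epochs[0]
    ch = electrode if isinstance(electrode, int) else ep0.channel_index(electrode)
    n_samp = ep0.data.shape[2]

    ratings = np.zeros((n_sub, n_e, 2))
    erp = np.zeros((n_sub, n_e, 2, n_samp))
    peaks = {k: np.zeros((n_sub, n_e, 2))
             for k in ("n2_amplitude", "p2_amplitude", "n2_latency", "p2_latency")}
    for s, (ep, spec) in enumerate(zip(cohort_epochs, cohort_specs)):
        power = cluster_power_per_trial(spec, cluster)
        for ei, e in enumerate(energies_all):
            m = ep.energies == e
            if m.sum() < 2:
                raise ValueError(f"subject {ep.subject}: energy {e} has "
                                 "<2 trials")
            labels = median_split(power[m])
            for split in (0, 1):
                sel = np.flatnonzero(m)[labels == split]
                ratings[s, ei, split] = ep.ratings[sel].mean()
                wave = ep.data[sel, ch, :].mean(axis=0)
                erp[s, ei, split] = wave
                pk = measure_peaks(wave, ep.times, window=peak_window)
                peaks["n2_amplitude"][s, ei, split] = pk.n2_amplitude
                peaks["p2_amplitude"][s, ei, split] = pk.p2_amplitude
                peaks["n2_latency"][s, ei, split] = pk.n2_latency
                peaks["p2_latency"][s, ei, split] = pk.p2_latency

    anova = {"rating": rm_anova(ratings, ("energy", "power"))}
    for k, v in peaks.items():
        anova[k] = rm_anova(v, ("energy", "power"))
    return SplitReport(cluster_label=cluster_label,
                       electrode=str(ep0.ch_names[ch]),
                       ratings=ratings,
                       n2_amplitude=peaks["n2_amplitude"],
                       p2_amplitude=peaks["p2_amplitude"],
                       n2_latency=peaks["n2_latency"],
                       p2_latency=peaks["p2_latency"],
                       erp=erp, erp_times=ep0.times, anova=anova)
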