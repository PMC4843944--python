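"""Event-related BOLD analysis: canonical-HRF GLM, onset-signal extraction,
and voxel-wise PLS prediction of ratings with cluster permutation.

The evoked analysis models laser events as stick functions convolved with the
canonical double-gamma haemodynamic response function (response peak near
5-6 s, undershoot near 16 s, undershoot ratio 1/6, 32 s support) and fits an
ordinary-least-squares GLM per voxel, one event regressor per stimulus
energy.  Slow scanner drift is removed beforehand by projecting out a
discrete-cosine basis below a 1/128 Hz cutoff (the convention of standard
fMRI toolchains; GLM-compatible, no phase distortion).

The prestimulus analysis uses the volume acquired at (or immediately before)
each stimulus onset: because of haemodynamic lag this sample reflects neural
activity preceding the stimulus.  Voxel-wise onset signals are z-scored
within energy and regressed on normalized ratings with the same SIMPLS PLS
used for EEG spectrograms; group one-sample t-maps are clustered in 3D
(6-connectivity) and assessed with stratified permutation, yielding
positively predictive ("Pos-BOLD") and negatively predictive ("Neg-BOLD")
voxel clusters whose mean onset signals feed the trial-wise decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusterstat import (TFCluster, TMap, form_clusters, tmap_one_sample,
                          permutation_pvalues, CLUSTER_ALPHA,
                          MIN_CLUSTER_SIZE, N_PERMUTATIONS)
from .plsmap import N_COMPONENTS, drop_zero_sd_columns, normalize_within_energy
from .predict import FeatureSet

HIGHPASS_CUTOFF_HZ = 1.0 / 128.0
HRF_LENGTH_S = 32.0


def canonical_hrf(tr: float, length_s: float = HRF_LENGTH_S,
                  oversample: int = 1) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr / oversample`` seconds.

    Difference of two gamma densities (shape 6 and 16, unit scale) with the
    undershoot weighted 1/6; peak-normalized to 1.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / oversample
    t = np.arange(0, length_s + dt / 2, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def highpass_bold(series: np.ndarray, tr: float,
                  cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
                  axis: int = -1) -> np.ndarray:
    """Remove drift below ``cutoff_hz`` by discrete-cosine basis projection.

    The constant term and all cosine regressors with frequency below the
    cutoff are regressed out (residualization), matching the standard GLM
    high-pass convention.  Signal above twice the cutoff is preserved to
    within a few percent.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if n * tr < 1.0 / cutoff_hz:
        raise ValueError("series shorter than one cutoff period")
    # DCT-II regressors: frequency of basis k is k / (2 n tr)
    k_max = int(np.floor(2.0 * n * tr * cutoff_hz))
    tgrid = np.arange(n)
    basis = [np.ones(n)]
    for k in range(1, k_max + 1):
        basis.append(np.cos(np.pi * k * (tgrid + 0.5) / n))
    Q, _ = np.linalg.qr(np.column_stack(basis))
    x = np.moveaxis(series, axis, -1)
    resid = x - (x @ Q) @ Q.T
    return np.moveaxis(resid, -1, axis)


def build_design(onsets: np.ndarray, energies: np.ndarray, n_volumes: int,
                 tr: float, oversample: int = 10,
                 add_constant: bool = True) -> pd.DataFrame:
    """HRF-convolved stick design matrix, one column per stimulus energy.

    Sticks are placed on a fine grid (``tr / oversample``), convolved with the
    canonical HRF and sampled at volume acquisition times.
    """
    onsets = np.asarray(onsets, dtype=float)
    energies = np.asarray(energies)
    dt = tr / oversample
    n_fine = n_volumes * oversample
    hrf = canonical_hrf(tr, oversample=oversample)
    cols = {}
    for e in np.unique(energies):
        stick = np.zeros(n_fine)
        idx = np.round(onsets[energies == e] / dt).astype(int)
        idx = idx[idx < n_fine]
        np.add.at(stick, idx, 1.0)
        reg = np.convolve(stick, hrf)[:n_fine]
        cols[f"energy_{e}"] = reg[::oversample]
    if add_constant:
        cols["constant"] = np.ones(n_volumes)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


@dataclass
class GLMResult:
    """Per-voxel OLS estimates for one subject."""

    betas: np.ndarray            # (*grid, n_regressors)
    t: np.ndarray                # (*grid, n_regressors)
    residual_var: np.ndarray
    columns: list[str]
    df: int


def fit_glm(series: np.ndarray, design: pd.DataFrame) -> GLMResult:
    """Voxel-wise ordinary least squares with per-regressor t statistics."""
    X = design.values
    n_vol, n_reg = X.shape
    grid = series.shape[:-1]
    if series.shape[-1] != n_vol:
        raise ValueError("series length does not match design")
    if np.linalg.matrix_rank(X) < n_reg:
        raise ValueError("design matrix is rank deficient")
    Y = series.reshape(-1, n_vol).T                     # (n_vol, n_vox)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y                                        # (n_reg, n_vox)
    resid = Y - X @ B
    df = n_vol - n_reg
    sigma2 = (resid ** 2).sum(axis=0) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, B / se, 0.0)
    return GLMResult(betas=B.T.reshape(grid + (n_reg,)),
                     t=tval.T.reshape(grid + (n_reg,)),
                     residual_var=sigma2.reshape(grid),
                     columns=list(design.columns), df=df)


def onset_signal(series: np.ndarray, onsets: np.ndarray, tr: float
                 ) -> np.ndarray:
    """Trial x voxel matrix of the volume acquired at (or before) each onset.

    Floor rule: the volume whose acquisition time is the largest multiple of
    TR not exceeding the onset.  Raises if an onset precedes the first
    volume.
    """
    onsets = np.asarray(onsets, dtype=float)
    if np.any(onsets < 0):
        raise ValueError("onset before first volume")
    vol = np.floor(onsets / tr + 1e-9).astype(int)
    if np.any(vol >= series.shape[-1]):
        raise ValueError("onset beyond last volume")
    flat = series.reshape(-1, series.shape[-1])
    return flat[:, vol].T                               # (n_trials, n_vox)


def voxel_pls_map(subject_onset: list[np.ndarray],
                  subject_ratings: list[np.ndarray],
                  subject_energies: list[np.ndarray],
                  grid_shape: tuple[int, int, int],
                  n_components: int = N_COMPONENTS,
                  alpha: float = CLUSTER_ALPHA,
                  min_size: int = MIN_CLUSTER_SIZE,
                  n_perm: int = N_PERMUTATIONS,
                  seed=None) -> tuple[TMap, list[TFCluster], list[TFCluster]]:
    """Group-level voxel PLS coefficient analysis of onset BOLD vs ratings.

    Per subject, onset signals and ratings are z-scored within energy and the
    SIMPLS coefficient map estimated; the subject maps enter a one-sample
    t-test, 3D clusters (6-connectivity, point-wise p < ``alpha``, more than
    ``min_size`` voxels) are formed separately for positive and negative t,
    and stratified permutation p-values are attached.  Returns the group
    t-map and the (Pos-BOLD, Neg-BOLD) cluster lists.
    """
    from .plsmap import simpls

    n_vox = int(np.prod(grid_shape))
    feats, rates, coefs = [], [], []
    for X, r, e in zip(subject_onset, subject_ratings, subject_energies):
        Z, keep = drop_zero_sd_columns(X, e)
        if not keep.all():
            full = np.zeros((Z.shape[0], n_vox))
            full[:, keep] = Z
            Z = full
        y = normalize_within_energy(r, e)
        coef, _ = simpls(Z, y, n_components)
        coefs.append(coef)
        feats.append(Z)
        rates.append(y)
    tmap = tmap_one_sample(np.asarray(coefs).reshape((-1,) + grid_shape))
    clusters = form_clusters(tmap, alpha=alpha, min_size=min_size)
    if clusters and n_perm > 0:
        permutation_pvalues(feats, rates, subject_energies, clusters,
                            grid_shape, n_perm=n_perm,
                            n_components=n_components, seed=seed)
    pos = [c for c in clusters if c.sign > 0]
    neg = [c for c in clusters if c.sign < 0]
    for c in pos:
        c.label = "Pos-BOLD"
    for c in neg:
        c.label = "Neg-BOLD"
    return tmap, pos, neg


def posneg_features(onset: np.ndarray, pos_clusters: list[TFCluster],
                    neg_clusters: list[TFCluster], labels: np.ndarray,
                    kept: np.ndarray | None = None) -> list[FeatureSet]:
    """Mean onset signal over Pos-BOLD / Neg-BOLD voxels plus the combination.

    ``onset`` is the (n_trials, n_vox) onset matrix of one subject; returns
    the three feature sets consumed by :mod:`prestim.predict`.
    """
    if not pos_clusters or not neg_clusters:
        raise ValueError("need at least one positive and one negative cluster")

    def mean_over(clusters):
        mask = np.zeros(clusters[0].grid_shape, dtype=bool)
        for c in clusters:
            mask[c.indices] = True
        return onset[:, mask.ravel()].mean(axis=1)

    pos_sig = mean_over(pos_clusters)
    neg_sig = mean_over(neg_clusters)
    if kept is not None:
        pos_sig, neg_sig = pos_sig[kept], neg_sig[kept]
    return [FeatureSet("Pos-BOLD", pos_sig[:, None], labels),
            FeatureSet("Neg-BOLD", neg_sig[:, None], labels),
            FeatureSet("Pos-BOLD+Neg-BOLD",
                       np.column_stack([pos_sig, neg_sig]), labels)]


# ---------------------------------------------------------------------------
# NIfTI / events I/O
# ---------------------------------------------------------------------------

def save_bold(dataset, nifti_path: str, events_path: str) -> None:
    """Write a BOLD dataset to a 4D NIfTI plus a TSV events file."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(dataset.series, dtype=np.float32),
                          affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, dataset.tr))
    nib.save(img, nifti_path)
    pd.DataFrame({"onset": dataset.onsets, "energy": dataset.energies,
                  "rating": dataset.ratings}).to_csv(events_path, sep="\t",
                                                     index=False)


def load_bold(nifti_path: str, events_path: str, subject: str = "S0"):
    import nibabel as nib
    from .synthgen import BOLDDataset

    img = nib.load(nifti_path)
    tr = float(img.header.get_zooms()[3])
    ev = pd.read_csv(events_path, sep="\t")
    return BOLDDataset(series=np.asarray(img.dataobj, dtype=float), tr=tr,
                       onsets=ev["onset"].values,
                       energies=ev["energy"].values.astype(int),
                       ratings=ev["rating"].values, subject=subject)
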