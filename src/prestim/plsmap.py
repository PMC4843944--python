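"""Within-energy normalization and PLS estimation of spectrogram-to-rating
multivariate linear regression.

Trial-wise features (flattened time-frequency power, or voxel values) and
ratings are z-scored within each stimulus-energy stratum so that the
trial-to-trial relationship is assessed free of the stimulus-energy effect.
The regression coefficient map alpha(t, f) is then estimated with SIMPLS
partial least squares (de Jong, 1993), which is deterministic (no random
initialisation) and coincides with ordinary least squares when the number of
components reaches the rank of the feature matrix.

For a single response variable the SIMPLS coefficient path also coincides
with NIPALS PLS1, so any standard PLS implementation can serve as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: default number of latent PLS components
N_COMPONENTS = 3


@dataclass
class CoefMap:
    """PLS regression coefficients on the feature grid of one subject/electrode."""

    coef: np.ndarray                     # grid-shaped (e.g. n_freqs x n_times)
    n_components: int
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("coefficient map must be finite")

    @property
    def flat(self) -> np.ndarray:
        return self.coef.ravel()


def normalize_within_energy(values: np.ndarray, energies: np.ndarray,
                            on_zero_sd: str = "raise") -> np.ndarray:
    """Z-score a trial vector or trial x feature matrix within each energy.

    Each energy stratum is processed independently with sample (ddof=1)
    standard deviation.  ``on_zero_sd`` controls zero-variance columns:
    ``"raise"`` (default) raises naming the stratum and column, ``"nan"``
    marks the column NaN so the caller can drop it.
    """
    values = np.asarray(values, dtype=float)
    vec = values.ndim == 1
    X = values[:, None] if vec else values.copy()
    energies = np.asarray(energies)
    out = np.empty_like(X)
    for e in np.unique(energies):
        m = energies == e
        if m.sum() < 2:
            raise ValueError(f"stratum {e} has fewer than 2 trials")
        mu = X[m].mean(axis=0)
        sd = X[m].std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            if on_zero_sd == "raise":
                cols = np.flatnonzero(zero)[:10].tolist()
                raise ValueError(
                    f"zero within-stratum SD in energy stratum {e}, "
                    f"column(s) {cols}")
            sd = np.where(zero, np.nan, sd)
        out[m] = (X[m] - mu) / sd
    return out[:, 0] if vec else out


def drop_zero_sd_columns(features: np.ndarray, energies: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a feature matrix, dropping zero-variance columns with a warning.

    Returns the normalized matrix restricted to kept columns and the boolean
    keep-mask over original columns.
    """
    Z = normalize_within_energy(features, energies, on_zero_sd="nan")
    bad = np.any(~np.isfinite(Z), axis=0)
    if bad.any():
        warnings.warn(f"dropping {bad.sum()} zero-variance feature column(s)",
                      RuntimeWarning, stacklevel=2)
    return Z[:, ~bad], ~bad


def simpls(X: np.ndarray, y: np.ndarray, n_components: int
           ) -> tuple[np.ndarray, np.ndarray]:
    """SIMPLS regression of a single response on ``X``.

    Parameters are centered internally (inputs are normally already
    stratum-standardized).  Returns ``(coef, explained_variance)`` where
    ``coef`` maps centered features to the centered response and
    ``explained_variance`` is the fraction of response variance captured by
    each successive latent component.

    If the response is (numerically) orthogonal to every feature the
    coefficient vector is all-zero and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError("n_components must be in 1..min(n_trials-1, n_features)")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    sy = float(yc @ yc)
    scale = np.sqrt((Xc ** 2).sum()) * np.sqrt(sy) + 1e-300
    if np.linalg.norm(s) / scale < 1e-12:
        warnings.warn("response orthogonal to all features; returning zero "
                      "coefficients", RuntimeWarning, stacklevel=2)
        return np.zeros(p), np.zeros(n_components)
    coef = np.zeros(p)
    V = np.zeros((p, n_components))
    evar = np.zeros(n_components)
    for a in range(n_components):
        r = s.copy()
        t = Xc @ r
        normt = np.linalg.norm(t)
        if normt / scale < 1e-12:
            break
        t /= normt
        r /= normt
        q = float(t @ yc)
        coef += r * q
        evar[a] = q * q / sy if sy > 0 else 0.0
        pl = Xc.T @ t
        v = pl - V[:, :a] @ (V[:, :a].T @ pl)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
        V[:, a] = v
        s = s - v * (v @ s)
    return coef, evar


def simpls_multi(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS coefficients for many responses sharing one feature matrix.

    ``Y`` is (n_trials, n_responses); each column is fit independently but the
    linear algebra is batched, which makes permutation schemes cheap.  Returns
    coefficients of shape (n_features, n_responses).  Columns orthogonal to
    the features yield zero coefficients (no warning; expected under
    permutation).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    B = Y.shape[1]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Xc.T @ Yc                                  # (p, B)
    coef = np.zeros((p, B))
    V = np.zeros((n_components, p, B))
    xnorm = np.sqrt((Xc ** 2).sum())
    ynorm = np.sqrt((Yc ** 2).sum(axis=0)) + 1e-300
    for a in range(n_components):
        T = Xc @ S                                 # (n, B)
        normt = np.linalg.norm(T, axis=0)
        dead = normt / (xnorm * ynorm) < 1e-12
        normt = np.where(dead, 1.0, normt)
        T /= normt
        R = S / normt
        q = np.einsum("nb,nb->b", T, Yc)
        q = np.where(dead, 0.0, q)
        coef += R * q
        P = Xc.T @ T                               # (p, B)
        v = P - np.einsum("apb,ab->pb", V[:a],
                          np.einsum("apb,pb->ab", V[:a], P)) if a else P
        nv = np.linalg.norm(v, axis=0)
        nv = np.where(nv == 0, 1.0, nv)
        v /= nv
        V[a] = v
        S = S - v * np.einsum("pb,pb->b", v, S)
    return coef


def fit_pls_mvlr(features: np.ndarray, ratings: np.ndarray,
                 n_components: int = N_COMPONENTS,
                 grid_shape: tuple[int, ...] | None = None,
                 freqs: np.ndarray | None = None,
                 times: np.ndarray | None = None) -> CoefMap:
    """PLS multivariate linear regression of ratings on flattened features.

    Inputs are expected stratum-normalized (see
    :func:`normalize_within_energy`).  The coefficient vector is reshaped to
    ``grid_shape`` when given.
    """
    coef, evar = simpls(features, ratings, n_components)
    if grid_shape is not None:
        coef = coef.reshape(grid_shape)
    return CoefMap(coef=coef, n_components=n_components,
                   explained_variance=evar, freqs=freqs, times=times)


def spectrogram_coefmap(power: np.ndarray, ratings: np.ndarray,
                        energies: np.ndarray,
                        n_components: int = N_COMPONENTS,
                        freqs: np.ndarray | None = None,
                        times: np.ndarray | None = None) -> CoefMap:
    """Normalize a (trial, freq, time) power array and fit the PLS MVLR.

    Zero-variance grid points (possible in degenerate synthetic inputs) are
    dropped for the fit and get a zero coefficient.
    """
    n_trials = power.shape[0]
    grid_shape = power.shape[1:]
    flat = power.reshape(n_trials, -1)
    Z, keep = drop_zero_sd_columns(flat, energies)
    y = normalize_within_energy(ratings, energies)
    coef_kept, evar = simpls(Z, y, n_components)
    coef = np.zeros(flat.shape[1])
    coef[keep] = coef_kept
    return CoefMap(coef=coef.reshape(grid_shape), n_components=n_components,
                   explained_variance=evar, freqs=freqs, times=times)


def coefmaps_by_energy(power: np.ndarray, ratings: np.ndarray,
                       energies: np.ndarray,
                       n_components: int = N_COMPONENTS,
                       freqs: np.ndarray | None = None,
                       times: np.ndarray | None = None) -> dict[int, CoefMap]:
    """One stratum-restricted coefficient map per stimulus energy.

    Within each stratum the features/ratings are z-scored over that stratum's
    trials only; used downstream to test intensity-independence of the
    prestimulus effects.
    """
    out: dict[int, CoefMap] = {}
    for e in np.unique(energies):
        m = energies == e
        n_here = int(m.sum())
        if n_here - 1 < n_components:
            raise ValueError(f"energy stratum {e} too small for "
                             f"{n_components} components")
        try:
            out[int(e)] = spectrogram_coefmap(
                power[m], ratings[m], np.zeros(n_here, dtype=int),
                n_components=n_components, freqs=freqs, times=times)
        except ValueError as err:
            raise ValueError(f"energy stratum {e}: {err}") from err
    return out
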