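"""Group-level point-wise t-statistics, cluster formation and cluster-level
permutation testing on coefficient maps.

The group analysis asks, at every time-frequency point (or voxel), whether the
subject-wise PLS coefficients differ from zero (one-sample t-test).  Adjacent
significant points of equal t-sign form clusters (4-connectivity on 2D grids,
6-connectivity on 3D voxel grids; no diagonals), clusters of more than
``min_size`` points are kept, and each cluster is summarized by the sum of its
t values (Sigma-T).  Significance is assessed by permuting ratings within each
stimulus-energy stratum, refitting the PLS model per subject and permutation,
and recomputing Sigma-T.

Two permutation schemes are available:

``"mask"`` (default)
    Sigma-T* is accumulated inside the predefined observed cluster masks and
    each cluster's two-tailed p is the add-one-corrected tail fraction
    ``(#{|Sigma-T*| >= |Sigma-T|} + 1) / (M + 1)``.  This scheme conditions
    on the observed cluster geometry and is anticonservative under the null;
    it is retained as the default because it is the convention the analyses
    in this package mirror.
``"maxstat"``
    Clusters are re-formed on every permuted map and the maximal |Sigma-T|
    across the permuted map is the reference distribution (family-wise
    control).

Because normalization is performed within energy, ratings are shuffled within
energy strata only; unstratified shuffling would break exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .plsmap import simpls, simpls_multi, N_COMPONENTS
from ._anova import rm_anova_twoway

#: point-wise threshold and minimum cluster extent
CLUSTER_ALPHA = 0.05
MIN_CLUSTER_SIZE = 20
N_PERMUTATIONS = 1000


@dataclass
class TMap:
    """Point-wise one-sample t statistics over subjects."""

    t: np.ndarray
    p: np.ndarray
    df: int
    degenerate: np.ndarray | None = None   # zero-variance points (t = +-inf)


@dataclass
class TFCluster:
    """A connected set of grid points with its Sigma-T statistic."""

    indices: tuple[np.ndarray, ...]        # per-axis member indices
    sum_t: float
    sign: int                              # +1 or -1
    grid_shape: tuple[int, ...]
    p_perm: float | None = None
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.indices[0])

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.indices] = True
        return m

    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        return tuple((int(ix.min()), int(ix.max())) for ix in self.indices)


def tmap_one_sample(maps: np.ndarray) -> TMap:
    """One-sample t-test of subject coefficient maps against zero.

    ``maps`` is (n_subjects, *grid).  Zero-variance points with nonzero mean
    are reported as t = +-inf with p = 0 and flagged in ``degenerate``;
    zero-variance zero-mean points get t = 0, p = 1.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if degenerate.any():
        deg_t = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
        t = np.where(degenerate, deg_t, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return TMap(t=t, p=p, df=n - 1, degenerate=degenerate)


def _structure(ndim: int) -> np.ndarray:
    # orthogonal neighbours only: 4-connectivity in 2D, 6-connectivity in 3D
    return ndimage.generate_binary_structure(ndim, 1)


def form_clusters(tmap: TMap, alpha: float = CLUSTER_ALPHA,
                  min_size: int = MIN_CLUSTER_SIZE) -> list[TFCluster]:
    """Connected components of the point-wise significance mask.

    Positive-t and negative-t points are labelled separately (a cluster never
    mixes signs).  Components of ``min_size`` or fewer points are discarded
    (strictly more than ``min_size`` points survive).
    """
    clusters: list[TFCluster] = []
    sig = tmap.p < alpha
    for sign in (1, -1):
        mask = sig & ((tmap.t > 0) if sign > 0 else (tmap.t < 0))
        lab, n_lab = ndimage.label(mask, structure=_structure(tmap.t.ndim))
        for k in range(1, n_lab + 1):
            idx = np.nonzero(lab == k)
            if len(idx[0]) <= min_size:
                continue
            clusters.append(TFCluster(indices=idx,
                                      sum_t=float(tmap.t[idx].sum()),
                                      sign=sign, grid_shape=tmap.t.shape))
    clusters.sort(key=lambda c: (-c.size, -abs(c.sum_t)))
    return clusters


@dataclass
class BandRule:
    """Selection rule: label clusters in a frequency band and time interval."""

    label: str
    f_range: tuple[float, float]          # Hz, inclusive lower edge
    interval: str                         # "pre" or "post"
    keep: str = "largest"                 # "largest" or "all"


DEFAULT_RULES = (
    BandRule("Pre-ABO", (0.0, 30.0), "pre"),
    BandRule("Pre-GBO", (30.0, np.inf), "pre"),
    BandRule("Post-GBO", (30.0, np.inf), "post"),
)


def select_band_clusters(clusters: list[TFCluster], freqs: np.ndarray,
                         times: np.ndarray,
                         rules: tuple[BandRule, ...] = DEFAULT_RULES
                         ) -> dict[str, list[TFCluster]]:
    """Apply band/interval labelling rules to time-frequency clusters.

    A cluster matches a rule when the centroid of its member points falls in
    the rule's frequency band and time interval (``pre``: t < 0 ms).  With
    ``keep="largest"`` only the cluster with most points is retained (ties
    broken by larger |Sigma-T|), mirroring the gamma-band selection
    convention.
    """
    out: dict[str, list[TFCluster]] = {r.label: [] for r in rules}
    for rule in rules:
        matched = []
        for c in clusters:
            fc = float(freqs[c.indices[0]].mean())
            tc = float(times[c.indices[1]].mean())
            in_band = rule.f_range[0] <= fc < rule.f_range[1]
            in_int = tc < 0 if rule.interval == "pre" else tc >= 0
            if in_band and in_int:
                matched.append(c)
        if rule.keep == "largest" and matched:
            matched.sort(key=lambda c: (-c.size, -abs(c.sum_t)))
            matched = matched[:1]
        for c in matched:
            c.label = rule.label
        out[rule.label] = matched
    return out


def _stratified_permutations(rng: np.random.Generator, energies: np.ndarray,
                             n_perm: int) -> np.ndarray:
    """(n_perm, n_trials) index array shuffling trials within each stratum."""
    n = len(energies)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for e in np.unique(energies):
        pos = np.flatnonzero(energies == e)
        for m in range(n_perm):
            perms[m, pos] = pos[rng.permutation(len(pos))]
    return perms


def permutation_pvalues(subject_features: list[np.ndarray],
                        subject_ratings: list[np.ndarray],
                        subject_energies: list[np.ndarray],
                        clusters: list[TFCluster],
                        grid_shape: tuple[int, ...],
                        n_perm: int = N_PERMUTATIONS,
                        n_components: int = N_COMPONENTS,
                        seed=None,
                        scheme: str = "mask",
                        alpha: float = CLUSTER_ALPHA,
                        min_size: int = MIN_CLUSTER_SIZE,
                        perm_chunk: int = 64) -> list[TFCluster]:
    """Attach permutation p-values to predefined clusters.

    ``subject_features`` are stratum-normalized (trial x feature) matrices per
    subject, ``subject_ratings`` the matching normalized rating vectors.  For
    each permutation the ratings are shuffled within energy stratum, the PLS
    fit and group t-map are recomputed, and Sigma-T* is collected (see module
    docstring for the two schemes).  p-values use the add-one correction
    ``(b + 1) / (M + 1)`` and therefore never reach zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not clusters:
        return clusters
    for c in clusters:
        if c.size == 0:
            raise ValueError("empty cluster mask")
    rng = np.random.default_rng(seed)
    n_sub = len(subject_features)
    p_feat = subject_features[0].shape[1]

    if scheme == "mask":
        union = np.zeros(grid_shape, dtype=bool)
        for c in clusters:
            union[c.indices] = True
        flat_union = np.flatnonzero(union.ravel())
        cluster_cols = [np.searchsorted(flat_union,
                                        np.ravel_multi_index(c.indices,
                                                             grid_shape))
                        for c in clusters]
        exceed = np.zeros(len(clusters), dtype=int)
        done = 0
        while done < n_perm:
            B = min(perm_chunk, n_perm - done)
            coefs = np.empty((n_sub, len(flat_union), B))
            for s in range(n_sub):
                perms = _stratified_permutations(rng, subject_energies[s], B)
                Yp = subject_ratings[s][perms.T]          # (n_trials, B)
                cf = simpls_multi(subject_features[s], Yp, n_components)
                coefs[s] = cf[flat_union]
            mean = coefs.mean(axis=0)
            sd = coefs.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_star = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)
            for ci, cols in enumerate(cluster_cols):
                sum_star = t_star[cols].sum(axis=0)
                exceed[ci] += int(np.sum(np.abs(sum_star)
                                         >= abs(clusters[ci].sum_t)))
            done += B
        for ci, c in enumerate(clusters):
            c.p_perm = (exceed[ci] + 1) / (n_perm + 1)
        return clusters

    if scheme == "maxstat":
        max_stat = np.zeros(n_perm)
        done = 0
        while done < n_perm:
            B = min(perm_chunk, n_perm - done)
            coefs = np.empty((n_sub, p_feat, B))
            for s in range(n_sub):
                perms = _stratified_permutations(rng, subject_energies[s], B)
                Yp = subject_ratings[s][perms.T]
                coefs[s] = simpls_multi(subject_features[s], Yp, n_components)
            for b in range(B):
                tm = tmap_one_sample(coefs[:, :, b].reshape((n_sub,) + grid_shape))
                cl = form_clusters(tm, alpha=alpha, min_size=min_size)
                max_stat[done + b] = max((abs(c.sum_t) for c in cl), default=0.0)
            done += B
        for c in clusters:
            b = int(np.sum(max_stat >= abs(c.sum_t)))
            c.p_perm = (b + 1) / (n_perm + 1)
        return clusters

    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# time-domain waveform clusters (two-way RM-ANOVA per time point)
# ---------------------------------------------------------------------------

@dataclass
class TimeCluster:
    """A temporally contiguous run of significant time points."""

    start_ms: float
    end_ms: float
    indices: np.ndarray
    sum_f: float
    p_perm: float | None = None


def timecourse_clusters(values: np.ndarray, times: np.ndarray,
                        alpha: float = CLUSTER_ALPHA, min_size: int = 10,
                        n_perm: int = N_PERMUTATIONS,
                        seed=None) -> list[TimeCluster]:
    """Cluster-corrected time course of the prestimulus-power main effect.

    ``values`` is (n_subjects, n_energies, 2, n_time): per-subject mean
    waveforms in each energy x power-split cell.  At every time point a
    two-way repeated-measures ANOVA F for the two-level split factor is
    computed; runs of at least ``min_size`` significant points form clusters
    scored by their summed F.  Significance comes from randomly exchanging
    the two split levels within each (subject, energy) cell, re-computing the
    F time course, and accumulating the summed F* inside the observed cluster
    masks (add-one-corrected two-tailed-free F test).
    """
    values = np.asarray(values, dtype=float)
    n_sub, n_a, n_b, n_time = values.shape
    if n_b != 2:
        raise ValueError("split factor must have exactly 2 levels")
    res = rm_anova_twoway(values)
    F_obs = res["B"].F
    p_obs = res["B"].p
    sig = p_obs < alpha
    lab, n_lab = ndimage.label(sig)
    clusters = []
    for k in range(1, n_lab + 1):
        idx = np.flatnonzero(lab == k)
        if len(idx) < min_size:
            continue
        clusters.append(TimeCluster(start_ms=float(times[idx[0]]),
                                    end_ms=float(times[idx[-1]]),
                                    indices=idx,
                                    sum_f=float(F_obs[idx].sum())))
    if not clusters or n_perm < 1:
        return clusters

    # F for the 2-level factor reduces to a squared paired t on cell
    # differences, which permits a fully vectorised sign-flip scheme.
    rng = np.random.default_rng(seed)
    d = values[:, :, 1, :] - values[:, :, 0, :]           # (n_sub, n_a, n_time)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub, n_a))
    D = np.einsum("msa,sat->mst", signs, d) / n_a          # subject means
    mean = D.mean(axis=1)
    sd = D.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_star = np.where(sd > 0, (np.sqrt(n_sub) * mean / sd) ** 2, 0.0)
    for c in clusters:
        sum_star = F_star[:, c.indices].sum(axis=1)
        b = int(np.sum(sum_star >= c.sum_f))
        c.p_perm = (b + 1) / (n_perm + 1)
    return clusters
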