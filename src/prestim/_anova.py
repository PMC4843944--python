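"""Balanced repeated-measures ANOVA and Tukey HSD helpers.

Univariate sums-of-squares decompositions for fully balanced within-subject
designs (every subject contributes one value per cell).  All routines are
vectorised over arbitrary trailing axes so that point-by-point waveform
statistics and permutation schemes stay cheap.

Sphericity is assumed; a Greenhouse-Geisser correction can be applied to the
returned (F, df) pairs by the caller (exposed as an option in
:func:`prestim.stateeffects.rm_anova`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class EffectResult:
    """F-test for one effect of a repeated-measures design."""

    F: float | np.ndarray
    df1: float
    df2: float
    p: float | np.ndarray


@dataclass
class AnovaTable:
    """Collection of effect tests plus optional post-hoc pairwise p-values."""

    effects: dict[str, EffectResult]
    posthoc: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


def _f_p(ss_num, df1, ss_den, df2):
    """F and p from sums of squares, handling the degenerate 0/0 case.

    SS_effect = SS_error = 0 (e.g. identical values in every cell) is reported
    as F = 0, p = 1; SS_error = 0 with a real effect as F = inf, p = 0.
    """
    ms_num = ss_num / df1
    ms_den = ss_den / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_den > 0, ms_num / np.maximum(ms_den, 1e-300),
                     np.where(ms_num > 0, np.inf, 0.0))
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isinf(F), 0.0, np.where((F == 0) & (ms_den == 0), 1.0, p))
    if np.ndim(F) == 0:
        return float(F), float(p)
    return F, p


def rm_anova_oneway(y: np.ndarray) -> EffectResult:
    """One-way repeated-measures ANOVA.

    Parameters
    ----------
    y : array, shape (n_subjects, k, ...)
        One value per subject and treatment level; trailing axes are
        broadcast (independent ANOVAs).
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape[0], y.shape[1]
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 levels")
    grand = y.mean(axis=(0, 1))
    m_treat = y.mean(axis=0)          # (k, ...)
    m_sub = y.mean(axis=1)            # (n, ...)
    ss_treat = n * ((m_treat - grand) ** 2).sum(axis=0)
    resid = y - m_treat[None] - m_sub[:, None] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F, p = _f_p(ss_treat, df1, ss_err, df2)
    return EffectResult(F, df1, df2, p)


def rm_anova_twoway(y: np.ndarray) -> dict[str, EffectResult]:
    """Two-way fully within-subject ANOVA on ``(n_subjects, a, b, ...)`` data.

    Returns effects ``"A"``, ``"B"`` and ``"AxB"``, each tested against its
    own interaction-with-subject error term (standard univariate approach).
    """
    y = np.asarray(y, dtype=float)
    n, a, b = y.shape[:3]
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >=2 subjects and >=2 levels per factor")
    grand = y.mean(axis=(0, 1, 2))
    m_a = y.mean(axis=(0, 2))             # (a, ...)
    m_b = y.mean(axis=(0, 1))             # (b, ...)
    m_ab = y.mean(axis=0)                 # (a, b, ...)
    m_s = y.mean(axis=(1, 2))             # (n, ...)
    m_sa = y.mean(axis=2)                 # (n, a, ...)
    m_sb = y.mean(axis=1)                 # (n, b, ...)

    ss_a = n * b * ((m_a - grand) ** 2).sum(axis=0)
    ss_b = n * a * ((m_b - grand) ** 2).sum(axis=0)
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None] + grand) ** 2).sum(axis=(0, 1))
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None] + grand) ** 2).sum(axis=(0, 1))
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None] + grand) ** 2).sum(axis=(0, 1))
    resid = (y - m_ab[None] - m_sa[:, :, None] - m_sb[:, None]
             + m_a[None, :, None] + m_b[None, None] + m_s[:, None, None] - grand)
    ss_sab = (resid ** 2).sum(axis=(0, 1, 2))

    out = {}
    df = {"A": a - 1, "B": b - 1, "AxB": (a - 1) * (b - 1)}
    err = {"A": (ss_sa, (a - 1) * (n - 1)),
           "B": (ss_sb, (b - 1) * (n - 1)),
           "AxB": (ss_sab, (a - 1) * (b - 1) * (n - 1))}
    for name, ss in (("A", ss_a), ("B", ss_b), ("AxB", ss_ab)):
        ss_e, df2 = err[name]
        F, p = _f_p(ss, df[name], ss_e, df2)
        out[name] = EffectResult(F, df[name], df2, p)
    return out


def tukey_rm(y: np.ndarray) -> dict[tuple[int, int], float]:
    """Tukey HSD pairwise comparisons for a one-way within-subject design.

    Each pair (i, j) is tested with its own paired-difference standard error
    (the nonpooled repeated-measures convention, robust to sphericity
    violations, which are structural when one condition is a combination of
    the others) against the studentized-range distribution with k groups and
    n - 1 df: ``q_ij = sqrt(2) * |mean d_ij| / (sd(d_ij) / sqrt(n))``.  For
    k = 2 this reduces exactly to the paired contrast.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    out: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            d = y[:, i] - y[:, j]
            se = d.std(ddof=1) / np.sqrt(n)
            if se == 0:
                p = 1.0 if d.mean() == 0 else 0.0
            else:
                q = np.sqrt(2.0) * abs(d.mean()) / se
                p = float(stats.studentized_range.sf(q, k, n - 1))
            out[(i, j)] = p
    return out


def greenhouse_geisser_eps(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon for an (n, k) within-subject table."""
    y = np.asarray(y, dtype=float)
    k = y.shape[1]
    S = np.cov(y, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum()
                     + k * k * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))
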