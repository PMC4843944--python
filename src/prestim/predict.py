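"""Single-trial low/high-perception classification from prestimulus features.

Ratings are z-scored within each stimulus energy; trials below 0 are "low",
above 0 "high" (exactly 0 is dropped).  A linear support vector machine with
leave-one-out cross-validation predicts the label of each held-out trial from
one or more prestimulus features (band power, onset BOLD signal), with
feature standardization computed on the training fold only.  Per-subject
accuracies of competing feature sets are compared with one-way
repeated-measures ANOVA and Tukey post-hocs: a significant advantage of the
combined set over each single set indicates that the features carry
independent, synergistic information about the forthcoming percept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from ._anova import AnovaTable, rm_anova_oneway, tukey_rm
from .plsmap import normalize_within_energy

logger = logging.getLogger(__name__)

#: SVM regularization constant (linear kernel)
SVM_C = 1.0


@dataclass
class FeatureSet:
    """Named trial x feature matrix with binary low/high labels."""

    name: str
    matrix: np.ndarray        # (n_trials, n_features)
    labels: np.ndarray        # 0 = low, 1 = high

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] == 1 and len(self.labels) > 1:
            self.matrix = self.matrix.T
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features must be finite")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("labels must match n_trials")


def binarize_ratings(ratings: np.ndarray, energies: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Within-energy-normalized rating sign -> binary labels.

    Returns ``(labels, kept)`` where ``labels`` (0 low / 1 high) covers kept
    trials only and ``kept`` is the boolean mask over input trials; z = 0
    trials are dropped.  If any stratum is single-class after binarization a
    warning is logged (the caller may skip the subject).
    """
    z = normalize_within_energy(np.asarray(ratings, dtype=float),
                                np.asarray(energies))
    kept = z != 0
    labels = (z[kept] > 0).astype(int)
    for e in np.unique(energies):
        le = labels[(np.asarray(energies)[kept]) == e]
        if len(le) and len(np.unique(le)) < 2:
            logger.warning("energy stratum %s is single-class after "
                           "binarization", e)
    return labels, kept


def loocv_predictions(X: np.ndarray, y: np.ndarray, C: float = SVM_C
                      ) -> np.ndarray:
    """Leave-one-out predictions of a linear-kernel SVM.

    For every trial the classifier is trained on all remaining trials, with
    features standardized using training-fold statistics only, and the
    held-out trial is predicted.  A degenerate single-class training fold
    falls back to majority-class prediction (logged).  Deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y).astype(int)
    n = len(y)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need >=2 trials per class")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            logger.info("fold %d: single-class training fold, majority vote", i)
            preds[i] = int(np.bincount(ytr).argmax())
            continue
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        # balanced class weights counter the leave-one-out artifact where the
        # held-out trial's class is always the training minority
        clf = SVC(kernel="linear", C=C, class_weight="balanced")
        clf.fit((X[tr] - mu) / sd, ytr)
        preds[i] = int(clf.predict(((X[i] - mu) / sd)[None, :])[0])
    return preds


def loocv_accuracy(features: FeatureSet | None = None, *,
                   X: np.ndarray | None = None, y: np.ndarray | None = None,
                   C: float = SVM_C) -> float:
    """Fraction of correctly predicted held-out trials under LOOCV."""
    if features is not None:
        X, y = features.matrix, features.labels
    preds = loocv_predictions(X, y, C=C)
    return float(np.mean(preds == y))


def compare_feature_sets(accuracies: np.ndarray,
                         names: tuple[str, ...] | None = None,
                         alpha: float = 0.05) -> AnovaTable:
    """One-way RM-ANOVA over per-subject accuracies of several feature sets.

    ``accuracies`` is (n_subjects, n_sets); Tukey HSD pairwise p-values are
    attached when the main effect is significant.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.ndim != 2:
        raise ValueError("accuracies must be (n_subjects, n_sets)")
    eff = rm_anova_oneway(accuracies)
    key = "feature_set" if names is None else "|".join(names)
    table = AnovaTable(effects={key: eff})
    if eff.p < alpha:
        table.posthoc[key] = tukey_rm(accuracies)
    return table


def make_feature_sets(single: dict[str, np.ndarray], labels: np.ndarray,
                      kept: np.ndarray | None = None) -> list[FeatureSet]:
    """Build the single-feature sets plus their all-features combination.

    ``single`` maps names (e.g. ``"Pre-ABO"``, ``"Pre-GBO"``) to per-trial
    scalar features; the returned list appends the combined set named
    ``"name1+name2"``.
    """
    feats = {k: (v[kept] if kept is not None else v) for k, v in single.items()}
    sets = [FeatureSet(name, vals[:, None], labels)
            for name, vals in feats.items()]
    combo = np.column_stack(list(feats.values()))
    sets.append(FeatureSet("+".join(feats), combo, labels))
    return sets
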