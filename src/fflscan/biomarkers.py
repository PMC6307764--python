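"""Exhaustive biomarker-panel search with cross-validated SVM evaluation.

Every non-empty subset of a small candidate regulator list is evaluated as
a case/control classification panel using a linear support-vector machine
under stratified 5-fold cross-validation.  Panel quality is mean fold
accuracy plus AUC (pooled decision values by default, per-fold average also
reported).  The optimal panel is the smallest one whose accuracy is within
a tolerance of the best observed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .expression import ExpressionStudy, StudyError

log = logging.getLogger(__name__)

#: Exhaustive enumeration guard: 2^20 - 1 panels is already ~1M evaluations.
MAX_CANDIDATES = 20


@dataclass
class PanelEvaluation:
    """Cross-validated performance of one feature panel."""

    features: tuple[str, ...]
    cv_accuracy: float
    cv_auc: float  # pooled decision values over folds
    cv_auc_per_fold: float  # mean of per-fold AUCs
    fold_assignments: list[int]
    seed: int

    @property
    def size(self) -> int:
        return len(self.features)


def enumerate_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    cand = sorted(set(candidates))
    if not 1 <= len(cand) <= MAX_CANDIDATES:
        raise ValueError(
            f"{len(cand)} candidates; exhaustive search supports 1..{MAX_CANDIDATES} "
            "(use a heuristic search beyond that)"
        )
    out: list[tuple[str, ...]] = []
    for size in range(1, len(cand) + 1):
        out.extend(itertools.combinations(cand, size))
    return out


def evaluate_panel(
    study: ExpressionStudy,
    features: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> PanelEvaluation:
    """Evaluate one panel with a linear SVM under stratified k-fold CV.

    Folds are stratified so each training fold contains both classes even
    with strongly unbalanced designs.  Accuracy is the mean over folds; the
    headline AUC pools continuous decision values across test folds.
    Fully reproducible given the seed.
    """
    feats = tuple(sorted(set(features)))
    missing = [f for f in feats if f not in study]
    if missing:
        raise StudyError(f"panel features not measured: {missing}")
    X = np.vstack([study.row(f) for f in feats]).T
    y = np.array([1 if lab == "case" else 0 for lab in study.labels])
    if len(np.unique(y)) < 2:
        raise StudyError("both classes required")
    # a panel with zero variance carries no signal; fold intercepts would
    # otherwise induce a spurious ordering of pooled decision values
    informative = float(np.ptp(X)) > 0

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(len(y), -1, dtype=int)
    accs: list[float] = []
    fold_aucs: list[float] = []
    pooled_scores = np.zeros(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:  # pragma: no cover - stratification prevents it
            raise StudyError(f"fold {fold} training split lacks a class")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[tr], y[tr])
        fold_of[te] = fold
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        dv = clf.decision_function(X[te])
        pooled_scores[te] = dv
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(_auc(y[te], dv))

    return PanelEvaluation(
        features=feats,
        cv_accuracy=float(np.mean(accs)),
        cv_auc=_auc(y, pooled_scores) if informative else 0.5,
        cv_auc_per_fold=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        fold_assignments=list(fold_of),
        seed=seed,
    )


def _auc(y: np.ndarray, scores: np.ndarray) -> float:
    if np.ptp(scores) == 0:
        return 0.5  # uninformative constant scores
    return float(roc_auc_score(y, scores))


def evaluate_all_panels(
    study: ExpressionStudy,
    candidates: Sequence[str],
    folds: int = 5,
    seed: int = 0,
) -> list[PanelEvaluation]:
    """Evaluate every non-empty candidate subset (deterministic order)."""
    return [
        evaluate_panel(study, subset, folds=folds, seed=seed)
        for subset in enumerate_subsets(candidates)
    ]


def select_optimal(
    evaluations: Sequence[PanelEvaluation], tolerance: float = 0.0
) -> PanelEvaluation:
    """Smallest panel within ``tolerance`` of the best accuracy.

    Ties resolve by higher pooled AUC, then lexicographic feature list; the
    default tolerance 0.0 means strict maximum accuracy.
    """
    if not evaluations:
        raise ValueError("no evaluations to select from")
    best = max(e.cv_accuracy for e in evaluations)
    eligible = [e for e in evaluations if e.cv_accuracy >= best - tolerance]
    eligible.sort(key=lambda e: (e.size, -e.cv_auc, e.features))
    return eligible[0]


def panel_table(
    evaluations: Sequence[PanelEvaluation], selected: PanelEvaluation | None = None
) -> pd.DataFrame:
    """Tabulate evaluations with a ``selected`` flag column."""
    sel = selected.features if selected is not None else None
    return pd.DataFrame(
        [
            (
                ";".join(e.features),
                e.size,
                e.cv_accuracy,
                e.cv_auc,
                e.cv_auc_per_fold,
                e.features == sel,
            )
            for e in evaluations
        ],
        columns=["features", "size", "cv_accuracy", "cv_auc", "cv_auc_per_fold", "selected"],
    )
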