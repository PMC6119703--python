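"""Greedy forward selection of (channel, band) features, and its competitors.

A candidate feature is one (channel, band) pair contributing its value at
every time step of the sequence.  Candidates are scored by the mean held-out
accuracy of an RBF-kernel SVM on the flattened (segments x selected features)
vectors under 3-fold stratified cross-validation.

The greedy strategy first picks the single best candidate, then repeatedly
adds the candidate that most improves the joint accuracy, stopping when the
feature budget is reached or no candidate improves on the current best
(redundant copies of an already-selected feature bring no improvement, so they
are skipped over — the key difference from ranking candidates independently,
which the optimal-based competitor does).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: Hyper-parameter grids for the RBF SVM evaluator.
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
SVM_GAMMA_GRID = (0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class EvaluatorConfig:
    """Frozen SVM evaluator settings used for every selection step."""

    C: float = 10.0
    gamma: float = 0.01
    n_folds: int = 3
    seed: int = 0


@dataclass(frozen=True)
class CandidateFeature:
    """One (channel, band) pair; ``index`` is its column in the feature axis."""

    channel: int
    band: str
    index: int


@dataclass
class SelectionResult:
    ordered: list[CandidateFeature]
    cv_accuracy_path: list[float]
    stop_reason: str  # "budget_reached" | "no_improvement"

    @property
    def indices(self) -> list[int]:
        return [f.index for f in self.ordered]

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": [
                    {
                        "rank": r + 1,
                        "channel": f.channel,
                        "band": f.band,
                        "cv_accuracy": acc,
                    }
                    for r, (f, acc) in enumerate(
                        zip(self.ordered, self.cv_accuracy_path)
                    )
                ],
                "stop_reason": self.stop_reason,
            },
            indent=2,
        )


def candidates_for(n_channels: int, band_labels: Sequence[str]) -> list[CandidateFeature]:
    """All (channel, band) candidates in channel-major column order."""
    out = []
    for c in range(n_channels):
        for b, label in enumerate(band_labels):
            out.append(CandidateFeature(c, label, c * len(band_labels) + b))
    return out


def _pipeline(cfg: EvaluatorConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)),
        ]
    )


def _check_cv_feasible(y: np.ndarray, n_folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for selection")
    if counts.min() < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs >= {n_folds} samples per class; "
            f"smallest class has {counts.min()}"
        )


def evaluate_feature_set(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EvaluatorConfig = EvaluatorConfig(),
    columns: Sequence[int] | None = None,
) -> float:
    """Mean 3-fold stratified CV accuracy of the RBF SVM on flattened sequences.

    ``X`` is (trials, segments, features); ``columns`` restricts the feature
    axis before flattening.  Standardization is fit on the training folds only.
    """
    y = np.asarray(y)
    _check_cv_feasible(y, cfg.n_folds)
    if columns is not None:
        X = X[:, :, list(columns)]
    flat = X.reshape(X.shape[0], -1)
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    scores = cross_val_score(_pipeline(cfg), flat, y, cv=cv)
    return float(scores.mean())


def tune_evaluator(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_folds: int = 3
) -> EvaluatorConfig:
    """Pick C and gamma once, by inner CV on the full feature set, then freeze."""
    y = np.asarray(y)
    _check_cv_feasible(y, n_folds)
    flat = X.reshape(X.shape[0], -1)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))]),
        {"svm__C": SVM_C_GRID, "svm__gamma": SVM_GAMMA_GRID},
        cv=cv,
    )
    grid.fit(flat, y)
    return EvaluatorConfig(
        C=grid.best_params_["svm__C"],
        gamma=grid.best_params_["svm__gamma"],
        n_folds=n_folds,
        seed=seed,
    )


def greedy_select(
    X: np.ndarray,
    y: np.ndarray,
    max_k: int = 6,
    cfg: EvaluatorConfig = EvaluatorConfig(),
    candidates: Sequence[CandidateFeature] | None = None,
) -> SelectionResult:
    """Greedy forward selection of up to ``max_k`` (channel, band) features.

    Ties in accuracy break toward the lowest (channel, band) index.  Stops
    early when the best joint accuracy does not strictly exceed the accuracy
    of the already-selected set.
    """
    import warnings

    if candidates is None:
        candidates = default_candidates(X)
    if not candidates:
        raise ValueError("need at least one candidate")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if max_k > len(candidates):
        warnings.warn(
            f"budget {max_k} exceeds {len(candidates)} candidates; truncated"
        )
        max_k = len(candidates)

    pool = list(candidates)  # already in (channel, band) index order
    selected: list[CandidateFeature] = []
    path: list[float] = []

    # step 0: best singleton (argmax, first occurrence wins ties)
    scores = [
        evaluate_feature_set(X, y, cfg, [f.index]) for f in pool
    ]
    best_i = int(np.argmax(scores))
    selected.append(pool.pop(best_i))
    path.append(scores[best_i])

    while len(selected) < max_k and pool:
        current_cols = [f.index for f in selected]
        joint = [
            evaluate_feature_set(X, y, cfg, current_cols + [f.index]) for f in pool
        ]
        best_i = int(np.argmax(joint))
        if joint[best_i] <= path[-1]:
            return SelectionResult(selected, path, "no_improvement")
        selected.append(pool.pop(best_i))
        path.append(joint[best_i])
    return SelectionResult(selected, path, "budget_reached")


def optimal_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    cfg: EvaluatorConfig = EvaluatorConfig(),
    candidates: Sequence[CandidateFeature] | None = None,
) -> SelectionResult:
    """Rank every candidate by its singleton CV accuracy and keep the top k.

    Redundancy is not penalized: an exact duplicate of an informative feature
    ranks just as high as the original.
    """
    import warnings

    if candidates is None:
        candidates = default_candidates(X)
    if not candidates:
        raise ValueError("need at least one candidate")
    if k > len(candidates):
        warnings.warn(f"k {k} exceeds {len(candidates)} candidates; truncated")
        k = len(candidates)
    scores = np.array([evaluate_feature_set(X, y, cfg, [f.index]) for f in candidates])
    # stable sort keeps (channel, band) index order among ties
    order = np.argsort(-scores, kind="stable")[:k]
    return SelectionResult(
        [candidates[i] for i in order],
        [float(scores[i]) for i in order],
        "budget_reached",
    )


def default_candidates(X: np.ndarray) -> list[CandidateFeature]:
    """One anonymous candidate per feature column (used when no naming given)."""
    return [CandidateFeature(i, "", i) for i in range(X.shape[2])]
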