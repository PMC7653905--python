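"""Per-residue ROC evaluation: AUC, TPR/FPR curves and FPR-at-TPR.

Scores and labels from all evaluated sequences are pooled into one
global curve (the convention under which residue-level MoRF predictors
are benchmarked); per-sequence AUCs remain available as a diagnostic.
Tied scores receive half credit, i.e. the AUC is the rank-based
Mann-Whitney estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .types import AnnotatedSequence, ScoreTrack

#: TPR grid for FPR-at-TPR summary tables.
TPR_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and trapezoidal AUC over pooled per-residue scores.

    Requires at least one positive and one negative label; with ties
    the AUC equals the Mann-Whitney statistic with half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be aligned 1-D vectors")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"need both classes: {n_pos} positive, {n_neg} negative"
        )
    fpr, tpr, thresholds = roc_curve(labels.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, thresholds=thresholds, tpr=tpr, fpr=fpr,
                     n_pos=n_pos, n_neg=n_neg)


def fpr_at_tpr(result: RocResult, target_tpr: float) -> float:
    """Smallest FPR among curve points with TPR >= target.

    Interpolation-free and conservative: the returned operating point
    actually exists on the curve.
    """
    if not 0 < target_tpr <= 1:
        raise EvaluationError("target TPR must be in (0, 1]")
    mask = result.tpr >= target_tpr - 1e-12
    if not mask.any():
        raise EvaluationError(
            f"TPR {target_tpr} unreachable (max {result.tpr.max():.4f})"
        )
    return float(result.fpr[mask].min())


def pool_tracks(
    tracks: Sequence[ScoreTrack],
    annotated: Mapping[str, AnnotatedSequence] | Iterable[AnnotatedSequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate scores and labels across sequences for a global curve."""
    if not isinstance(annotated, Mapping):
        annotated = {a.id: a for a in annotated}
    scores, labels = [], []
    for t in tracks:
        if t.seq_id not in annotated:
            raise EvaluationError(f"no annotation for sequence {t.seq_id!r}")
        seq = annotated[t.seq_id]
        if len(seq) != len(t):
            raise EvaluationError(
                f"track/annotation length mismatch for {t.seq_id!r}"
            )
        scores.append(t.scores)
        labels.append(seq.labels)
    if not scores:
        raise EvaluationError("no tracks to evaluate")
    return np.concatenate(scores), np.concatenate(labels)


def evaluate_tracks(
    tracks: Sequence[ScoreTrack],
    annotated: Mapping[str, AnnotatedSequence] | Iterable[AnnotatedSequence],
    tpr_grid: Sequence[float] = TPR_GRID,
) -> dict:
    """Pooled evaluation report: AUC, class counts, FPR at a TPR grid."""
    scores, labels = pool_tracks(tracks, annotated)
    result = roc_auc(scores, labels)
    report = {
        "auc": result.auc,
        "n_pos": result.n_pos,
        "n_neg": result.n_neg,
        "fpr_at_tpr": {f"{t:.1f}": fpr_at_tpr(result, t) for t in tpr_grid},
    }
    return report


def plot_roc(result: RocResult, path: str) -> None:
    """Save the pooled ROC curve as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result.fpr, result.tpr, lw=1.5,
            label=f"AUC = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
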