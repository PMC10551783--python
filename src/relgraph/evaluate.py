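"""Probability-matrix ensembling and weighted multiclass evaluation.

The relation classifier emits, for every sentence, a softmax probability
vector over the 125-label relation vocabulary ("not a relation" included).
Several submodels can be combined by a weighted average of their
probability matrices.  Evaluation follows the standard weighted-average
convention: per-class precision, recall and F1 aggregated with weights
proportional to each class's true-instance support, plus a micro-averaged
one-vs-rest precision-recall curve that excludes the null label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax as _scipy_softmax
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .errors import DimensionError, InvalidWeightsError

__all__ = [
    "NOT_A_RELATION",
    "LabelVocabulary",
    "EvalReport",
    "PRCurve",
    "softmax_rows",
    "ensemble_weighted_average",
    "predict_labels",
    "weighted_prf",
    "pr_curve",
    "write_probability_matrix",
    "read_probability_matrix",
]

#: Canonical null label: a sentence that asserts no relation between its entities.
NOT_A_RELATION = "not a relation"

_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered relation-label vocabulary with a designated null label."""

    labels: tuple[str, ...]
    not_a_relation_index: int = 0

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise DimensionError("vocabulary labels must be unique")
        if not (0 <= self.not_a_relation_index < len(self.labels)):
            raise DimensionError("not_a_relation_index out of range")

    @classmethod
    def from_labels(cls, labels: Sequence[str], null_label: str = NOT_A_RELATION) -> "LabelVocabulary":
        labels = tuple(labels)
        if labels.count(null_label) != 1:
            raise DimensionError(f"null label {null_label!r} must occur exactly once")
        return cls(labels=labels, not_a_relation_index=labels.index(null_label))

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def null_label(self) -> str:
        return self.labels[self.not_a_relation_index]


def _as_matrix(values: np.ndarray | Sequence, name: str = "matrix") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(f"{name} must be a non-empty 2-D array, got shape {arr.shape}")
    return arr


def validate_probability_matrix(values: np.ndarray) -> np.ndarray:
    """Check non-negativity and unit row sums (tolerance 1e-6)."""
    arr = _as_matrix(values, "probability matrix")
    if (arr < 0).any():
        raise DimensionError("probability matrix has negative entries")
    sums = arr.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
        worst = float(np.abs(sums - 1.0).max())
        raise DimensionError(f"probability matrix rows must sum to 1 (max deviation {worst:g})")
    return arr


def softmax_rows(logits: np.ndarray | Sequence) -> np.ndarray:
    """Row-wise softmax with max-subtraction stability (delegated to scipy)."""
    arr = _as_matrix(logits, "logits")
    if not np.isfinite(arr).all():
        raise DimensionError("logits must be finite")
    return _scipy_softmax(arr, axis=1)


def ensemble_weighted_average(
    matrices: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Weighted average of submodel probability matrices: Σ wᵢ Mᵢ / Σ wᵢ."""
    if len(matrices) == 0:
        raise DimensionError("need at least one matrix")
    if len(weights) != len(matrices):
        raise DimensionError(
            f"{len(weights)} weights for {len(matrices)} matrices"
        )
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise InvalidWeightsError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise InvalidWeightsError("weights must not all be zero")
    mats = [validate_probability_matrix(m) for m in matrices]
    shape = mats[0].shape
    for i, m in enumerate(mats[1:], start=1):
        if m.shape != shape:
            raise DimensionError(f"matrix {i} has shape {m.shape}, expected {shape}")
    out = np.zeros(shape, dtype=float)
    for wi, m in zip(w, mats):
        out += wi * m
    return out / total


def predict_labels(matrix: np.ndarray, vocab: LabelVocabulary) -> list[str]:
    """Row-wise argmax labels; ties resolve to the lowest label index."""
    arr = _as_matrix(matrix)
    if arr.shape[1] != len(vocab):
        raise DimensionError(
            f"matrix has {arr.shape[1]} columns but vocabulary has {len(vocab)} labels"
        )
    idx = arr.argmax(axis=1)  # numpy argmax already takes the first maximum
    return [vocab.labels[i] for i in idx]


@dataclass(frozen=True)
class EvalReport:
    """Per-label and support-weighted precision/recall/F1."""

    labels: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_label": {
                lab: {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for lab, p, r, f, s in zip(
                    self.labels, self.precision, self.recall, self.f1, self.support
                )
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def weighted_prf(
    y_true: Sequence[str], y_pred: Sequence[str], vocab: LabelVocabulary
) -> EvalReport:
    """Support-weighted precision/recall/F1 over the full vocabulary.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
    mean; undefined ratios are reported as 0.  Weighted aggregates are
    Σ (support_c / N) × metric_c over classes with the true-class support.
    """
    if len(y_true) != len(y_pred):
        raise DimensionError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise DimensionError("empty label sequences")
    known = set(vocab.labels)
    for seq_name, seq in (("y_true", y_true), ("y_pred", y_pred)):
        unknown = set(seq) - known
        if unknown:
            raise DimensionError(f"{seq_name} contains labels outside the vocabulary: {sorted(unknown)}")
    precision, recall, f1, support = _sk_prfs(
        y_true, y_pred, labels=list(vocab.labels), average=None, zero_division=0
    )
    n = support.sum()
    weights = support / n
    return EvalReport(
        labels=vocab.labels,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        weighted_precision=float((weights * precision).sum()),
        weighted_recall=float((weights * recall).sum()),
        weighted_f1=float((weights * f1).sum()),
    )


@dataclass(frozen=True)
class PRCurve:
    """Micro-averaged one-vs-rest precision-recall curve."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    excluded_label: str | None = None

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall.tolist(), self.precision.tolist()))


def pr_curve(
    y_true: Sequence[str],
    matrix: np.ndarray,
    vocab: LabelVocabulary,
    exclude_null: bool = True,
) -> PRCurve:
    """Micro-averaged one-vs-rest PR curve over all labels except the null.

    Every (sample, label) pair contributes one binary decision scored by the
    label's probability; the null label's column is removed before pooling
    (configurable via ``exclude_null``).
    """
    arr = _as_matrix(matrix)
    if len(y_true) != arr.shape[0]:
        raise DimensionError("y_true length must match matrix row count")
    if arr.shape[1] != len(vocab):
        raise DimensionError("matrix column count must match vocabulary size")
    true_idx = np.array([vocab.index_of(lab) for lab in y_true])
    onehot = np.zeros(arr.shape, dtype=int)
    onehot[np.arange(len(true_idx)), true_idx] = 1
    keep = np.ones(len(vocab), dtype=bool)
    excluded = None
    if exclude_null:
        keep[vocab.not_a_relation_index] = False
        excluded = vocab.null_label
    precision, recall, thresholds = _sk_pr_curve(
        onehot[:, keep].ravel(), arr[:, keep].ravel()
    )
    return PRCurve(
        precision=precision, recall=recall, thresholds=thresholds, excluded_label=excluded
    )


def write_probability_matrix(
    matrix: np.ndarray, vocab: LabelVocabulary, path: str | Path
) -> None:
    """TSV with a header row of label names, one sample per data row."""
    arr = _as_matrix(matrix)
    if arr.shape[1] != len(vocab):
        raise DimensionError("matrix column count must match vocabulary size")
    pd.DataFrame(arr, columns=list(vocab.labels)).to_csv(path, sep="\t", index=False)


def read_probability_matrix(path: str | Path) -> tuple[np.ndarray, LabelVocabulary]:
    """Inverse of :func:`write_probability_matrix`."""
    df = pd.read_csv(path, sep="\t")
    labels = tuple(df.columns)
    null = NOT_A_RELATION if NOT_A_RELATION in labels else labels[0]
    vocab = LabelVocabulary(labels=labels, not_a_relation_index=labels.index(null))
    return df.to_numpy(dtype=float), vocab
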