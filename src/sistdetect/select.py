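"""Mutual-information mRMR ranking and wrapper forward feature selection.

Relevance of a feature is its mutual information with the class; redundancy
is the mean pairwise mutual information inside the selected set.  Ranking is
the standard first-order incremental search for the difference criterion
(MID): the next feature maximizes ``I(x; c) - mean_{s in S} I(x; s)``.
Continuous features are discretized into equal-width bins over the training
range before estimating mutual information with the plug-in (histogram)
estimator, in bits.

The mRMR ranking is refined by a wrapper forward feature selection (FFS)
that scans candidates in ranked order and keeps a feature only when it
improves the validation F1 score of a small probe classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from sklearn.metrics import f1_score

__all__ = [
    "mutual_information",
    "discretize",
    "mrmr_rank",
    "forward_select",
    "SelectedFeatureSet",
]

_DEFAULT_BINS = 10


def mutual_information(x_discrete, y_discrete) -> float:
    """Plug-in mutual information of two discrete sequences, in bits."""
    x = np.asarray(x_discrete).ravel()
    y = np.asarray(y_discrete).ravel()
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
    return float(terms.sum())


def discretize(X: np.ndarray, bins: int = _DEFAULT_BINS,
               bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Equal-width binning of each column over its (training) range."""
    X = np.asarray(X, dtype=float)
    if bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = bounds
    span = hi - lo
    span = np.where(span <= 0, 1.0, span)
    codes = np.clip(((X - lo) / span * bins), 0, bins - 1).astype(np.uint8)
    return codes


def _mi_columns(codes: np.ndarray, y: np.ndarray, bins: int,
                n_classes: int) -> np.ndarray:
    """Mutual information of every column of ``codes`` against ``y``.

    Joint histograms of all columns are accumulated in one pass by fusing
    (column, bin, class) into a single integer key.
    """
    n, p = codes.shape
    cell = bins * n_classes
    key = codes * np.uint16(n_classes) + y.astype(np.uint16)[:, None]
    key = key.astype(np.int32)
    key += np.arange(p, dtype=np.int32)[None, :] * cell
    counts = np.bincount(key.ravel(), minlength=p * cell)
    joints = counts.reshape(p, bins, n_classes)

    pj = joints / n
    px = pj.sum(axis=2, keepdims=True)
    py = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pj > 0, pj * np.log2(pj / (px * py)), 0.0)
    return terms.sum(axis=(1, 2))


def mrmr_rank(features: np.ndarray, labels: np.ndarray, m: int,
              bins: int = _DEFAULT_BINS,
              discretized: bool = False) -> list[int]:
    """Rank ``m`` columns by first-order incremental mRMR (MID criterion).

    The first feature maximizes relevance ``I(x; c)``; each subsequent one
    maximizes ``I(x; c) - (1/|S|) sum_{s in S} I(x; s)``.  Ties break to the
    lowest column index.  ``features`` may be pre-discretized codes
    (``discretized=True``) or continuous values binned over their own range.
    """
    X = np.asarray(features)
    y = np.asarray(labels).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels must have equal length")
    p = X.shape[1]
    if m > p:
        raise ValueError(f"cannot rank {m} of {p} columns")
    codes = X.astype(np.uint8) if discretized else discretize(X, bins)
    _, yi = np.unique(y, return_inverse=True)
    n_classes = yi.max() + 1
    relevance = _mi_columns(codes, yi, bins, n_classes)

    order: list[int] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(m):
        if step == 0:
            score = relevance.copy()
        else:
            last = codes[:, order[-1]].astype(np.intp)
            redundancy_sum += _mi_columns(codes, last, bins, int(last.max()) + 1)
            score = relevance - redundancy_sum / len(order)
        score[~remaining] = -np.inf
        j = int(np.argmax(score))      # argmax takes the lowest index on ties
        order.append(j)
        remaining[j] = False
    return order


def forward_select(ranked: list[int], train_matrix: np.ndarray,
                   train_labels: np.ndarray, val_matrix: np.ndarray,
                   val_labels: np.ndarray, classifier_factory=None,
                   patience: int = 5, max_features: int | None = None) -> list[int]:
    """Wrapper FFS over an mRMR-ranked candidate list.

    Scans candidates in order; a candidate is kept iff it strictly improves
    the validation F1 of the probe classifier.  Scanning stops after
    ``patience`` consecutive non-improvements or once ``max_features`` are
    kept.  At least one feature (the top-ranked) is always returned.
    """
    if len(ranked) == 0:
        raise ValueError("ranked candidate list is empty")
    if classifier_factory is None:
        from .classify import ELMClassifier

        def classifier_factory():
            return ELMClassifier(n_hidden=100, random_state=0,
                                 class_weight="balanced")

    def score(cols: list[int]) -> float:
        clf = classifier_factory()
        n_hidden = getattr(clf, "n_hidden", None)
        if n_hidden is not None and n_hidden > train_matrix.shape[0]:
            clf.set_params(n_hidden=train_matrix.shape[0])
        clf.fit(train_matrix[:, cols], train_labels)
        pred = clf.predict(val_matrix[:, cols])
        return f1_score(val_labels, pred, zero_division=0.0)

    selected = [ranked[0]]
    best = score(selected)
    fails = 0
    for cand in ranked[1:]:
        if max_features is not None and len(selected) >= max_features:
            break
        trial = score(selected + [cand])
        if trial > best:
            selected.append(cand)
            best = trial
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                break
    return selected


@dataclass
class SelectedFeatureSet:
    """The mRMR ranking and the final forward-selected column subset."""

    mrmr_order: list[int]
    selected: list[int]
    mi_bins: int
    relevance: list[float] = field(default_factory=list)
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        if not set(self.selected) <= set(self.mrmr_order):
            raise ValueError("selected must be a subset of the mRMR ranking")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mrmr_order": self.mrmr_order,
            "selected": self.selected,
            "mi_bins": self.mi_bins,
            "relevance": self.relevance,
            "column_names": self.column_names,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectedFeatureSet":
        d = json.loads(Path(path).read_text())
        return cls(**d)
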