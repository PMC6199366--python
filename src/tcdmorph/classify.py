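"""Youden-threshold fitting, the three-threshold decision tree, LOOCV.

All classifiers here are threshold rules on one or two scalar features
(VCI, VAI), with LVO the positive class.  Thresholds are fit by
exhaustively maximizing the sensitivity-weighted Youden statistic

    J_alpha = alpha * TPR - (1 - alpha) * FPR,        alpha in [0.5, 1]

over all candidate cut points (midpoints between consecutive distinct
sorted feature values, plus -inf/+inf sentinels).  alpha = 0.5 is
ordinary Youden J up to a factor of two; alpha = 1 maximizes sensitivity
outright.  Ties in J_alpha break toward higher specificity, i.e. toward
the candidate classifying fewer subjects positive.

The decision tree cascades three such thresholds, fit sequentially on
successively reduced training data: (1) VCI below VCI_MIN predicts LVO;
(2) of the remainder, VCI above VCI_MAX predicts the control class;
(3) the rest is decided by VAI below/above VAI_CRIT.  Equality at any
threshold falls through (predicts the control side of that rule).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .exams import IHC, LVO

BELOW = "below_is_positive"
ABOVE = "above_is_positive"


@dataclass(frozen=True)
class ThresholdModel:
    threshold: float
    direction: str = BELOW
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.direction not in (BELOW, ABOVE):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not 0.5 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0.5, 1]")

    def predict(self, values: Sequence[float]) -> np.ndarray:
        """Boolean positive-class predictions (strict inequality)."""
        values = np.asarray(values, dtype=float)
        if self.direction == BELOW:
            return values < self.threshold
        return values > self.threshold


@dataclass(frozen=True)
class TreeModel:
    """Fitted thresholds of the sequential decision tree."""

    vci_min: float
    vci_max: float
    vai_crit: float
    alpha: float = 0.5
    #: names of stages that saw a single class during fitting and were
    #: replaced by a pass-through sentinel (fit metadata, not serialized)
    skipped_stages: Tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not 0.5 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0.5, 1]")
        if self.vci_min > self.vci_max:
            raise ValidationError("vci_min must not exceed vci_max")


def _positive_mask(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == LVO


def fit_threshold(
    values: Sequence[float],
    labels: Sequence,
    direction: str = BELOW,
    alpha: float = 0.5,
    candidate_min: Optional[float] = None,
) -> ThresholdModel:
    """Exhaustive J_alpha-maximizing threshold over midpoint candidates.

    ``labels`` may be booleans (True = positive) or {"LVO", "IHC"} strings.
    ``candidate_min`` restricts the candidate set to cut points >= that
    value (used to keep the tree's two VCI thresholds ordered).
    """
    values = np.asarray(values, dtype=float)
    pos = _positive_mask(labels)
    if len(values) != len(pos):
        raise ValidationError("values and labels differ in length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("threshold fitting requires both classes")

    uniq = np.unique(values)
    candidates = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    if candidate_min is not None:
        candidates = candidates[candidates >= candidate_min]
        if len(candidates) == 0:
            candidates = np.array([np.inf])

    if direction == BELOW:
        classified = values[:, None] < candidates[None, :]
    elif direction == ABOVE:
        classified = values[:, None] > candidates[None, :]
    else:
        raise ValidationError(f"unknown direction {direction!r}")

    tpr = classified[pos].sum(axis=0) / n_pos
    fpr = classified[~pos].sum(axis=0) / n_neg
    j = alpha * tpr - (1.0 - alpha) * fpr

    best = j.max()
    tied = np.flatnonzero(j == best)
    n_classified = classified.sum(axis=0)
    # tie-break toward higher specificity: fewest subjects called positive
    winner = tied[np.argmin(n_classified[tied])]
    return ThresholdModel(
        threshold=float(candidates[winner]), direction=direction, alpha=alpha
    )


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def _as_arrays(rows: Sequence) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    vci = np.asarray([r.vci for r in rows], dtype=float)
    vai = np.asarray([r.vai for r in rows], dtype=float)
    labels = np.asarray([r.label for r in rows])
    return vci, vai, labels


def fit_tree(rows: Sequence, alpha: float = 0.5) -> TreeModel:
    """Fit VCI_MIN, VCI_MAX, VAI_CRIT sequentially, each maximizing J_alpha.

    A stage whose training subset contains a single class is skipped: its
    threshold becomes a sentinel that passes all of its data onward (the
    final VAI stage, which has nothing to pass onward to, gets the
    sentinel predicting its one remaining class).
    """
    vci, vai, labels = _as_arrays(rows)
    pos = _positive_mask(labels)
    if len(rows) == 0 or pos.all() or not pos.any():
        raise ValidationError("tree fitting requires both classes")
    skipped: List[str] = []

    # stage 1: low VCI => LVO
    vci_min = -np.inf
    if pos.any() and (~pos).any():
        vci_min = fit_threshold(vci, pos, BELOW, alpha).threshold
    remaining = vci >= vci_min

    # stage 2: high VCI => control; candidates kept >= vci_min
    vci_max = np.inf
    r_pos = pos[remaining]
    if r_pos.any() and (~r_pos).any():
        vci_max = fit_threshold(
            vci[remaining], r_pos, BELOW, alpha, candidate_min=vci_min
        ).threshold
    elif remaining.any():
        skipped.append("vci_max")
    remaining = remaining & (vci <= vci_max)

    # stage 3: VAI decides the rest
    r_pos = pos[remaining]
    if r_pos.any() and (~r_pos).any():
        vai_crit = fit_threshold(vai[remaining], r_pos, BELOW, alpha).threshold
    elif r_pos.any():          # only LVO left: predict LVO
        vai_crit = np.inf
        skipped.append("vai_crit")
    else:                      # only controls (or nothing) left: predict IHC
        vai_crit = -np.inf
        skipped.append("vai_crit")

    return TreeModel(
        vci_min=float(vci_min),
        vci_max=float(vci_max),
        vai_crit=float(vai_crit),
        alpha=alpha,
        skipped_stages=tuple(skipped),
    )


def predict_tree(model: TreeModel, rows: Sequence) -> np.ndarray:
    """Apply the three-rule cascade; returns an array of "LVO"/"IHC"."""
    vci, vai, _ = _as_arrays(rows)
    out = np.where(
        vci < model.vci_min,
        LVO,
        np.where(
            vci > model.vci_max,
            IHC,
            np.where(vai < model.vai_crit, LVO, IHC),
        ),
    )
    return out


# single-feature classifiers share the tree's sentinel convention
VAI_ONLY = "vai_only"
VCI_ONLY = "vci_only"
TREE = "tree"
CLASSIFIERS = (VAI_ONLY, VCI_ONLY, TREE)


def _fit_predict(train_rows: Sequence, test_rows: Sequence, classifier: str, alpha: float) -> np.ndarray:
    if classifier == TREE:
        model = fit_tree(train_rows, alpha)
        return predict_tree(model, test_rows)
    if classifier not in (VAI_ONLY, VCI_ONLY):
        raise ValidationError(f"unknown classifier {classifier!r}")
    attr = "vai" if classifier == VAI_ONLY else "vci"
    values = np.asarray([getattr(r, attr) for r in train_rows], dtype=float)
    pos = _positive_mask([r.label for r in train_rows])
    if pos.all():
        threshold = np.inf       # degenerate fold: everything positive
    elif not pos.any():
        threshold = -np.inf      # degenerate fold: everything negative
    else:
        threshold = fit_threshold(values, pos, BELOW, alpha).threshold
    test = np.asarray([getattr(r, attr) for r in test_rows], dtype=float)
    return np.where(test < threshold, LVO, IHC)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def acc(self) -> float:
        n = self.tp + self.fn + self.fp + self.tn
        return (self.tp + self.tn) / n if n else math.nan


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    t = _positive_mask(y_true)
    p = _positive_mask(y_pred)
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fn=int((t & ~p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
    )


@dataclass(frozen=True)
class LoocvResult:
    predictions: tuple
    counts: ConfusionCounts

    @property
    def sen(self) -> float:
        return self.counts.sen

    @property
    def spe(self) -> float:
        return self.counts.spe

    @property
    def acc(self) -> float:
        return self.counts.acc


def loocv(rows: Sequence, classifier: str = TREE, alpha: float = 0.5) -> LoocvResult:
    """Leave-one-out cross-validation with a pooled confusion matrix.

    Each of the n folds refits the chosen classifier on the other n-1
    subjects and predicts the held-out one; held-out predictions are
    pooled into a single confusion matrix.
    """
    rows = list(rows)
    if len(rows) < 3:
        raise ValidationError("LOOCV requires at least 3 subjects")
    pos = _positive_mask([r.label for r in rows])
    if pos.all() or not pos.any():
        raise ValidationError("LOOCV requires both classes")
    preds = []
    for i in range(len(rows)):
        train = rows[:i] + rows[i + 1:]
        preds.append(_fit_predict(train, [rows[i]], classifier, alpha)[0])
    counts = confusion([r.label for r in rows], preds)
    return LoocvResult(predictions=tuple(preds), counts=counts)


def sensitivity_sweep(
    rows: Sequence,
    classifier: str = TREE,
    alpha_grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Cross-validated and in-sample performance across an alpha grid.

    The default grid runs from 0.5 (ordinary Youden J) to 1.0 (maximal
    sensitivity) in steps of 0.01 -- 51 rows.
    """
    if alpha_grid is None:
        alpha_grid = np.linspace(0.5, 1.0, 51)
    rows = list(rows)
    records = []
    for alpha in alpha_grid:
        alpha = float(alpha)
        cv = loocv(rows, classifier, alpha)
        in_pred = _fit_predict(rows, rows, classifier, alpha)
        in_counts = confusion([r.label for r in rows], in_pred)
        records.append(
            {
                "alpha": alpha,
                "sen": cv.sen,
                "spe": cv.spe,
                "acc": cv.acc,
                "sen_insample": in_counts.sen,
                "spe_insample": in_counts.spe,
                "acc_insample": in_counts.acc,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

MODEL_KEYS = ("vci_min", "vci_max", "vai_crit", "alpha")


def write_model_json(model: TreeModel, path) -> None:
    payload = {k: getattr(model, k) for k in MODEL_KEYS}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model_json(path) -> TreeModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    missing = [k for k in MODEL_KEYS if k not in payload]
    if missing:
        raise FormatError(f"model JSON missing key(s): {', '.join(missing)}")
    return TreeModel(**{k: float(payload[k]) for k in MODEL_KEYS})
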