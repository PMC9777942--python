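"""Confusion counting, Dice/sensitivity/accuracy, splits, k-fold harness.

The three metrics are the standard voxel-overlap quantities::

    Dice        = 2 TP / (2 TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    Accuracy    = (TP + TN) / (TP + TN + FP + FN)

Conventions for degenerate inputs (needed for tumor-free cases): Dice of
two empty masks is 1.0; sensitivity with no true positives in the
reference is undefined and returned as NaN; accuracy of an empty
comparison is an error.

The harness supports both evaluation protocols used with this kind of
data: a fixed random 70/15/15 train/validation/test split (floor, floor,
remainder arithmetic) and 10-fold cross-validation with per-fold metric
records aggregated as column means rounded to one decimal of a percent
(round half up, matching how such tables are printed).
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ShapeError

# ---------------------------------------------------------------------------
# confusion counts and the three metrics
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies over voxels or samples."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred, truth) -> ConfusionCounts:
    """Element-wise confusion counts between two binary arrays.

    Accepts anything array-like of matching shape containing {0,1} (or
    booleans); :class:`~gliocascade.io_volumes.BinaryMask` callers pass
    ``.mask``.
    """
    p = np.asarray(getattr(pred, "mask", pred))
    t = np.asarray(getattr(truth, "mask", truth))
    if p.shape != t.shape:
        raise ShapeError(f"pred shape {p.shape} != truth shape {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """Recall; NaN when the reference has no positives."""
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified elements."""
    if c.total == 0:
        raise DataError("accuracy of an empty comparison is undefined")
    return (c.tp + c.tn) / c.total


@dataclasses.dataclass
class MetricsRecord:
    """One evaluation's Dice/sensitivity/accuracy, as fractions in [0, 1]."""

    dice: float
    sensitivity: float
    accuracy: float

    @classmethod
    def from_masks(cls, pred, truth) -> "MetricsRecord":
        c = confusion(pred, truth)
        return cls(dice=dice(c), sensitivity=sensitivity(c), accuracy=accuracy(c))


# ---------------------------------------------------------------------------
# split and k-fold protocols
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SplitPlan:
    """A fixed random partition into train/validation/test."""

    n_total: int
    fractions: tuple
    counts: tuple
    assignment: dict  # unit id -> "train" | "val" | "test"

    def ids(self, part: str) -> list:
        return [u for u, p in self.assignment.items() if p == part]


def split_counts(n_total: int, fractions=(0.70, 0.15, 0.15)) -> tuple:
    """Floor/floor/remainder counts: (floor(N*f_tr), floor(N*f_val), rest)."""
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigError(f"need three nonnegative fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fractions}")
    n_train = int(np.floor(n_total * fractions[0]))
    n_val = int(np.floor(n_total * fractions[1]))
    return n_train, n_val, n_total - n_train - n_val


def make_split(ids: Sequence, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitPlan:
    """Randomly assign units to train/val/test with floor-floor-remainder counts."""
    ids = list(ids)
    counts = split_counts(len(ids), fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < counts[0]:
            part = "train"
        elif rank < counts[0] + counts[1]:
            part = "val"
        else:
            part = "test"
        assignment[ids[idx]] = part
    return SplitPlan(n_total=len(ids), fractions=tuple(fractions), counts=counts,
                     assignment=assignment)


def round_percent(value: float, decimals: int = 1) -> float:
    """Round half up at ``decimals`` places (how result tables are printed)."""
    q = Decimal(10) ** -decimals
    # snap binary float noise (e.g. 88.74999999999999) before the half-up
    return float(Decimal(f"{float(value):.9f}").quantize(q, rounding=ROUND_HALF_UP))


def aggregate_percent(values: Sequence[float], decimals: int = 1) -> float:
    """Mean of per-fold percentages, rounded half up to ``decimals``."""
    vals = [float(v) for v in values]
    return round_percent(float(np.mean(vals)), decimals)


@dataclasses.dataclass
class FoldReport:
    """Per-fold metric records plus their printed-precision aggregate.

    ``per_fold`` stores fractions in [0, 1]; ``aggregate`` holds the
    column means expressed in percent, rounded to one decimal.
    """

    per_fold: list  # list of (fold_index, MetricsRecord)
    aggregate: MetricsRecord = None

    def __post_init__(self):
        if self.aggregate is None:
            self.aggregate = MetricsRecord(
                dice=self._agg("dice"),
                sensitivity=self._agg("sensitivity"),
                accuracy=self._agg("accuracy"),
            )

    def _agg(self, field: str) -> float:
        vals = [getattr(rec, field) * 100.0 for _, rec in self.per_fold]
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            return float("nan")
        return aggregate_percent(vals)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per fold plus an ``Avg. (%)`` row (percent)."""
        rows = [
            {"fold": f"Fold {i + 1}",
             "dice": round_percent(rec.dice * 100, 2),
             "sensitivity": round_percent(rec.sensitivity * 100, 2),
             "accuracy": round_percent(rec.accuracy * 100, 2)}
            for i, (_, rec) in enumerate(self.per_fold)
        ]
        rows.append({"fold": "Avg. (%)", "dice": self.aggregate.dice,
                     "sensitivity": self.aggregate.sensitivity,
                     "accuracy": self.aggregate.accuracy})
        return pd.DataFrame(rows, columns=["fold", "dice", "sensitivity", "accuracy"])

    @classmethod
    def from_percent_columns(cls, dice_pct, sensitivity_pct, accuracy_pct) -> "FoldReport":
        """Build a report from already-printed per-fold percentages."""
        per_fold = [
            (i, MetricsRecord(dice=d / 100.0, sensitivity=s / 100.0, accuracy=a / 100.0))
            for i, (d, s, a) in enumerate(zip(dice_pct, sensitivity_pct, accuracy_pct))
        ]
        return cls(per_fold=per_fold)


def kfold_evaluate(cases: Sequence, train_fn: Callable, eval_fn: Callable,
                   k: int = 10, seed: int = 0) -> FoldReport:
    """k-fold cross-validation over ``cases``.

    ``train_fn(train_cases)`` returns a fitted model; ``eval_fn(model,
    test_cases)`` returns a :class:`MetricsRecord` for the held-out
    fold.  Cases are shuffled once with ``seed`` and partitioned into k
    folds; each case appears in exactly one test fold.
    """
    n = len(cases)
    if k < 2 or k > n:
        raise ConfigError(f"k={k} must satisfy 2 <= k <= n_cases={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    per_fold = []
    for i, test_idx in enumerate(folds):
        test_set = set(int(j) for j in test_idx)
        train_cases = [cases[j] for j in range(n) if j not in test_set]
        test_cases = [cases[int(j)] for j in test_idx]
        model = train_fn(train_cases)
        rec = eval_fn(model, test_cases)
        per_fold.append((i, rec))
    return FoldReport(per_fold=per_fold)
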