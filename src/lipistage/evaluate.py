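"""Stratified splitting, class rounding, truth tables, exact and ±1-stage
tolerance accuracy, and regression metrics.

Two conventions are fixed here and used everywhere downstream:

* **standard error** means the root-mean-square prediction error
  √(Σ(y − ŷ)²/n) on the continuous scale — with unit-spaced class codes this
  is the natural companion to the reported accuracies;
* **r²** is the squared Pearson correlation between truth and prediction
  (the variance-explained form 1 − SSE/SST is also exported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SplitError
from .preprocess import CodedDataset


class RegressionMetrics(NamedTuple):
    r2: float
    se: float
    r2_defined: bool
    r2_vexp: float  # 1 − SSE/SST variant


@dataclass
class TruthTable:
    """Confusion matrix of true vs predicted class codes."""

    classes: list[int]
    counts: np.ndarray  # [true × predicted]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.classes, name="true"),
                            columns=pd.Index(self.classes, name="predicted"))

    def to_dict(self) -> dict:
        return {"classes": self.classes,
                "counts": [[int(c) for c in row] for row in self.counts]}


@dataclass
class EvaluationReport:
    """Train/test r², RMSE, truth tables and exact / ±1-tolerance accuracies
    for one fitted model."""

    r2_train: float
    r2_test: float
    se_train: float
    se_test: float
    truth_train: TruthTable
    truth_test: TruthTable
    acc_exact_train: float
    acc_exact_test: float
    acc_tol1_train: float
    acc_tol1_test: float
    split_seed: int

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train, "r2_test": self.r2_test,
            "se_train": self.se_train, "se_test": self.se_test,
            "truth_train": self.truth_train.to_dict(),
            "truth_test": self.truth_test.to_dict(),
            "acc_exact_train": self.acc_exact_train,
            "acc_exact_test": self.acc_exact_test,
            "acc_tol1_train": self.acc_tol1_train,
            "acc_tol1_test": self.acc_tol1_test,
            "split_seed": self.split_seed,
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(dataset: CodedDataset, test_frac: float = 0.2,
                     seed: int = 0) -> tuple[CodedDataset, CodedDataset]:
    """Seeded stratified train/test partition.

    Per-class test count is ``round(test_frac · n_class)`` (half rounds up)
    with a minimum of one test sample per class; sampling is without
    replacement from a ``default_rng(seed)`` stream.  The partition is a
    disjoint cover of the input.
    """
    if not (0 < test_frac < 1):
        raise SplitError(f"test_frac must lie in (0, 1), got {test_frac}")
    rng = np.random.default_rng(seed)
    test_ids: list = []
    for cls in sorted(set(dataset.y)):
        members = list(dataset.y.index[dataset.y == cls])
        if len(members) < 2:
            raise SplitError(f"class {cls} has only {len(members)} sample(s); "
                             "cannot split")
        n_test = max(1, int(np.floor(test_frac * len(members) + 0.5)))
        if n_test >= len(members):
            n_test = len(members) - 1
        chosen = rng.choice(len(members), size=n_test, replace=False)
        test_ids.extend(members[i] for i in sorted(chosen))
    test_set = set(test_ids)
    train_ids = [s for s in dataset.y.index if s not in test_set]
    test_ids = [s for s in dataset.y.index if s in test_set]
    return dataset.subset(train_ids), dataset.subset(test_ids)


# ---------------------------------------------------------------------------
# rounding / truth tables / accuracy
# ---------------------------------------------------------------------------

def round_to_class(y_hat, classes: Sequence[int]) -> np.ndarray:
    """Map continuous predictions to the nearest class code.

    Exact midpoints map to the lower code; predictions outside the code
    range are clipped to the nearest extreme.
    """
    codes = np.asarray(sorted(classes), dtype=float)
    if codes.size == 0:
        raise InputError("classes must be non-empty")
    yh = np.asarray(y_hat, dtype=float)
    boundaries = (codes[:-1] + codes[1:]) / 2.0
    idx = np.searchsorted(boundaries, yh, side="left")
    return codes[idx].astype(int)


def truth_table(y_true, y_pred, classes: Sequence[int] | None = None) -> TruthTable:
    """counts[i][j] = number of samples with true class i predicted as j."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise InputError("empty input to truth_table")
    if yt.shape != yp.shape:
        raise InputError("y_true and y_pred differ in length")
    if classes is None:
        classes = sorted(set(yt) | set(yp))
    classes = sorted(int(c) for c in classes)
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(yt, yp):
        counts[pos[int(t)], pos[int(p)]] += 1
    return TruthTable(classes, counts)


def accuracy(tt: TruthTable, tolerance: int = 0) -> float:
    """Fraction of samples with |true − predicted| ≤ tolerance."""
    classes = np.asarray(tt.classes)
    diff = np.abs(classes[:, None] - classes[None, :])
    hit = tt.counts[diff <= tolerance].sum()
    return float(hit) / tt.n


def regression_metrics(y_true, y_hat) -> RegressionMetrics:
    """(r², RMSE) with r² the squared Pearson correlation.

    When either vector is constant the correlation is undefined; r² is then
    reported as 0 with ``r2_defined=False``.
    """
    yt = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_hat, dtype=float).ravel()
    if yt.shape != yh.shape or yt.size == 0:
        raise InputError("y_true and y_hat must be equal-length and non-empty")
    resid = yt - yh
    se = float(np.sqrt(np.mean(resid ** 2)))
    st, sh = yt.std(), yh.std()
    sst = float(np.sum((yt - yt.mean()) ** 2))
    r2_vexp = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    if st == 0 or sh == 0:
        return RegressionMetrics(0.0, se, False, r2_vexp)
    r = float(np.corrcoef(yt, yh)[0, 1])
    return RegressionMetrics(r * r, se, True, r2_vexp)


def evaluate_predictions(
    y_train, yhat_train, y_test, yhat_test,
    classes: Sequence[int], split_seed: int = 0,
) -> EvaluationReport:
    """Assemble the full report from continuous predictions on both
    partitions."""
    m_train = regression_metrics(y_train, yhat_train)
    m_test = regression_metrics(y_test, yhat_test)
    tt_train = truth_table(y_train, round_to_class(yhat_train, classes), classes)
    tt_test = truth_table(y_test, round_to_class(yhat_test, classes), classes)
    return EvaluationReport(
        r2_train=m_train.r2, r2_test=m_test.r2,
        se_train=m_train.se, se_test=m_test.se,
        truth_train=tt_train, truth_test=tt_test,
        acc_exact_train=accuracy(tt_train, 0),
        acc_exact_test=accuracy(tt_test, 0),
        acc_tol1_train=accuracy(tt_train, 1),
        acc_tol1_test=accuracy(tt_test, 1),
        split_seed=split_seed,
    )
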