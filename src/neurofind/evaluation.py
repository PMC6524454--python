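"""Evaluation statistics: 2x2 confusion metrics, Cohen kappa with percent
agreement, the McNemar paired test, and F-measure.

Metrics with a zero denominator are reported as ``None`` (an explicit
undefined marker) rather than silently 0 or NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from neurofind.corpus_io import Label
from neurofind.errors import AlignmentError


class BinarizePolicy(enum.Enum):
    """How 3-way labels collapse into a 2x2 evaluation."""

    POSITIVE_VS_REST = "positive-vs-rest"
    POSITIVE_PLUS_INDETERMINATE = "positive-plus-indeterminate"


def binarize_labels(
    labels: Sequence[Label], policy: BinarizePolicy = BinarizePolicy.POSITIVE_VS_REST
) -> list[int]:
    if policy is BinarizePolicy.POSITIVE_VS_REST:
        positive = {Label.POSITIVE}
    else:
        positive = {Label.POSITIVE, Label.INDETERMINATE}
    return [1 if Label(lab) in positive else 0 for lab in labels]


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return _ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
        }


def confusion_metrics(gold: Sequence[int], pred: Sequence[int]) -> ConfusionSummary:
    """Counts and derived metrics from paired binary vectors."""
    if len(gold) != len(pred):
        raise AlignmentError(f"gold has {len(gold)} items, pred has {len(pred)}")
    if len(gold) == 0:
        raise AlignmentError("need at least one paired label")
    g = np.asarray(gold, dtype=int)
    p = np.asarray(pred, dtype=int)
    return ConfusionSummary(
        tp=int(((g == 1) & (p == 1)).sum()),
        fp=int(((g == 0) & (p == 1)).sum()),
        fn=int(((g == 1) & (p == 0)).sum()),
        tn=int(((g == 0) & (p == 0)).sum()),
    )


@dataclass(frozen=True)
class AgreementSummary:
    percent_agree: float  # in [0, 100]
    kappa: float | None  # None when chance agreement is 1 (degenerate)
    n: int
    categories: tuple
    contingency: np.ndarray  # K x K counts, rows = annotator 1


def cohen_kappa(ann1: Sequence[Hashable], ann2: Sequence[Hashable]) -> AgreementSummary:
    """Unweighted Cohen kappa over nominal categories (K >= 2 supported).

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals; when both
    annotators are constant and identical, p_e = 1 and kappa is undefined
    (None) while percent agreement is 100.
    """
    if len(ann1) != len(ann2):
        raise AlignmentError(f"annotator vectors differ in length: {len(ann1)} vs {len(ann2)}")
    n = len(ann1)
    if n < 2:
        raise AlignmentError("need at least 2 paired annotations")
    categories = tuple(sorted(set(ann1) | set(ann2), key=str))
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    table = np.zeros((k, k), dtype=int)
    for a, b in zip(ann1, ann2):
        table[index[a], index[b]] += 1
    p_o = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    kappa = None if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementSummary(
        percent_agree=100.0 * p_o,
        kappa=kappa,
        n=n,
        categories=categories,
        contingency=table,
    )


class McNemarMethod(enum.Enum):
    EXACT_BINOMIAL = "exact"
    CHI_SQUARE_CC = "chi2"


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    p_value: float
    method: McNemarMethod
    degenerate: bool = False  # b + c == 0


def mcnemar(
    gold: Sequence[int],
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    method: McNemarMethod = McNemarMethod.EXACT_BINOMIAL,
) -> McNemarResult:
    """Paired comparison of two classifiers against the same gold standard.

    Exact method: p = min(1, 2 * min(BinomCDF(min(b,c); b+c, 0.5), 0.5)).
    Chi-square method uses the continuity-corrected statistic
    (|b-c| - 1)^2 / (b+c) with 1 df.
    """
    if not (len(gold) == len(pred_a) == len(pred_b)):
        raise AlignmentError("gold, pred_a and pred_b must have equal lengths")
    g = np.asarray(gold, dtype=int)
    a = np.asarray(pred_a, dtype=int)
    bv = np.asarray(pred_b, dtype=int)
    b = int(((a == g) & (bv != g)).sum())
    c = int(((a != g) & (bv == g)).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0,
                             method=method, degenerate=True)
    if method is McNemarMethod.EXACT_BINOMIAL:
        k = min(b, c)
        p = min(1.0, 2.0 * min(float(stats.binom.cdf(k, n, 0.5)), 0.5))
        return McNemarResult(b=b, c=c, statistic=float(k), p_value=p, method=method)
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, statistic=statistic, p_value=p, method=method)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2pr/(p+r); the p = r = 0 corner is defined as 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_predictions(
    gold: Sequence[Label],
    pred: Sequence[Label],
    policy: BinarizePolicy = BinarizePolicy.POSITIVE_VS_REST,
) -> ConfusionSummary:
    """Binarize 3-way gold/pred label vectors and compute 2x2 metrics."""
    return confusion_metrics(binarize_labels(gold, policy), binarize_labels(pred, policy))
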