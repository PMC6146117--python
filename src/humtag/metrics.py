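"""Binary and probabilistic evaluation of tagger output.

Binary metrics (MCC, F1, precision, recall, error rate) are computed
from a confusion table obtained by thresholding probabilities at 0.50
(score >= threshold is predicted positive).  Probabilistic quality is
measured by AUC (Mann-Whitney formulation, ties counted half), the
Brier score, and a fixed-width-bin calibration curve with its adjusted
R^2 against the identity.  Agreement statistics summarise a manual
review of extreme disagreements between tagger and index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Mann-Whitney formulation: the probability that a uniformly random
    positive outscores a uniformly random negative, with ties counted
    one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(labels.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mcc_from_labels(pred, labels) -> float:
    """MCC of binary predictions against labels (zero-marginal -> 0)."""
    return binary_metrics(_confusion(np.asarray(pred, bool),
                                     np.asarray(labels, bool))).mcc


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _confusion(pred: np.ndarray, labels: np.ndarray) -> ConfusionTable:
    return ConfusionTable(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )


def binarize(scores, labels, threshold: float = 0.50) -> ConfusionTable:
    """Threshold probabilities (score >= threshold is positive)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    return _confusion(scores >= threshold, labels)


@dataclass(frozen=True)
class BinaryMetrics:
    mcc: float
    f1: float
    precision: float
    recall: float
    error_rate: float


def binary_metrics(t: ConfusionTable) -> BinaryMetrics:
    """Standard binary metrics from a confusion table.

    MCC returns 0 when any marginal is zero (safe convention); F1,
    precision and recall return 0 on empty denominators.
    """
    if t.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(t.tp), float(t.fp), float(t.tn), float(t.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    error_rate = (fp + fn) / t.total
    return BinaryMetrics(mcc=float(mcc), f1=float(f1), precision=float(precision),
                         recall=float(recall), error_rate=float(error_rate))


def brier(scores, labels) -> float:
    """Mean squared difference between probability and 0/1 outcome."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape[0] == 0:
        raise ValueError("empty input")
    return float(np.mean((scores - labels) ** 2))


@dataclass(frozen=True)
class EvaluationReport:
    """The full metric set for one scored, labeled corpus."""

    auc: float
    mcc: float
    f1: float
    recall: float
    precision: float
    brier: float
    error_rate: float
    n: int
    threshold: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "mcc", "f1", "recall", "precision", "brier",
                 "error_rate", "n", "threshold")}


def evaluate(scores, labels, threshold: float = 0.50) -> EvaluationReport:
    """Compute the full report: AUC/Brier plus thresholded binary metrics."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    bm = binary_metrics(binarize(scores, labels, threshold))
    return EvaluationReport(
        auc=auc(scores, labels), mcc=bm.mcc, f1=bm.f1, recall=bm.recall,
        precision=bm.precision, brier=brier(scores, labels),
        error_rate=bm.error_rate, n=int(labels.shape[0]), threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationBin:
    lo: float
    hi: float
    n: int
    mean_score: float | None
    proportion: float | None


@dataclass(frozen=True)
class CalibrationCurve:
    """Binned predicted probability vs observed positive proportion."""

    bins: tuple[CalibrationBin, ...]
    bin_width: float

    @property
    def n(self) -> int:
        return sum(b.n for b in self.bins)

    def populated(self) -> list[CalibrationBin]:
        return [b for b in self.bins if b.n > 0]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_lo\tbin_hi\tn\tmean_score\tproportion\n")
            for b in self.bins:
                ms = "" if b.mean_score is None else f"{b.mean_score:.6f}"
                pr = "" if b.proportion is None else f"{b.proportion:.6f}"
                fh.write(f"{b.lo:.4f}\t{b.hi:.4f}\t{b.n}\t{ms}\t{pr}\n")


def calibration_curve(scores, labels, bin_width: float = 0.05) -> CalibrationCurve:
    """Fixed-width reliability bins partitioning [0, 1].

    Empty bins are retained with n=0 and undefined score/proportion;
    the bin width must evenly divide 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must evenly divide 1")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    idx = np.minimum((scores / bin_width).astype(int), n_bins - 1)
    bins = []
    for i in range(n_bins):
        mask = idx == i
        k = int(mask.sum())
        bins.append(CalibrationBin(
            lo=i * bin_width, hi=(i + 1) * bin_width, n=k,
            mean_score=float(scores[mask].mean()) if k else None,
            proportion=float(labels[mask].mean()) if k else None,
        ))
    return CalibrationCurve(bins=tuple(bins), bin_width=bin_width)


def calibration_adjusted_r2(curve: CalibrationCurve,
                            min_bin_n: int = 1) -> float:
    """Adjusted R^2 of observed proportions regressed on mean scores.

    Simple linear fit over populated bins (one predictor).  With a
    well-calibrated tagger the curve hugs the diagonal and this
    approaches 1.  ``min_bin_n`` restricts the fit to bins with at
    least that many records: a bin holding a handful of records has a
    0-or-1 observed proportion that says nothing about calibration,
    so small-sample reliability analyses should raise it.
    """
    pop = [b for b in curve.populated() if b.n >= min_bin_n]
    if len(pop) < 3:
        raise ValueError("need at least 3 populated bins")
    x = np.array([b.mean_score for b in pop])
    y = np.array([b.proportion for b in pop])
    n = len(pop)
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def mean_calibration_error(scores, reference, bin_width: float = 0.05,
                           min_bin_n: int = 1) -> float:
    """Count-weighted mean |mean predicted - mean reference| over bins.

    ``reference`` may be 0/1 labels or true posterior probabilities
    (for synthetic corpora with a known generative model).
    """
    scores = np.asarray(scores, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    n_bins = round(1.0 / bin_width)
    idx = np.minimum((scores / bin_width).astype(int), n_bins - 1)
    errs, weights = [], []
    for i in range(n_bins):
        mask = idx == i
        k = int(mask.sum())
        if k >= min_bin_n:
            errs.append(abs(scores[mask].mean() - reference[mask].mean()))
            weights.append(k)
    if not errs:
        raise ValueError("no populated bins")
    return float(np.average(errs, weights=weights))


# ---------------------------------------------------------------------------
# Score histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreHistogram:
    """Per-label-class score distributions, percent of articles per bin."""

    edges: np.ndarray
    positive_pct: np.ndarray
    negative_pct: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_lo\tbin_hi\tpositive_pct\tnegative_pct\n")
            for i in range(len(self.positive_pct)):
                fh.write(f"{self.edges[i]:.4f}\t{self.edges[i + 1]:.4f}\t"
                         f"{self.positive_pct[i]:.4f}\t{self.negative_pct[i]:.4f}\n")


def score_histogram(scores, labels, bin_width: float = 0.05) -> ScoreHistogram:
    """Normalized (percent) score histograms for each label class."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must evenly divide 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    for cls in (True, False):
        sub = scores[labels == cls]
        counts, _ = np.histogram(sub, bins=edges)
        pct = 100.0 * counts / sub.size if sub.size else np.zeros(n_bins)
        out.append(pct)
    return ScoreHistogram(edges=edges, positive_pct=out[0], negative_pct=out[1])


# ---------------------------------------------------------------------------
# Extreme-disagreement agreement statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementTable:
    """Manual review counts for the two extreme-disagreement strata.

    Low stratum: index says positive but tagger score < 0.01 (the
    model predicts NOT_HUMAN).  High stratum: index says negative but
    score > 0.99 (the model predicts HUMAN).  Each row holds reviewer
    counts (humans, not_humans, uncertain).
    """

    low: tuple[int, int, int]
    high: tuple[int, int, int]


@dataclass(frozen=True)
class AgreementStats:
    low_pct: float
    high_pct: float
    overall_pct: float


def agreement_stats(table: AgreementTable) -> AgreementStats:
    """Percent agreement between the manual review and the model.

    In the low stratum the model predicts NOT_HUMAN, so reviewer
    "not humans" verdicts agree; in the high stratum it predicts
    HUMAN, so "humans" verdicts agree.  UNCERTAIN counts as a
    non-match.  Percentages on a 0-100 scale.
    """
    low_total = sum(table.low)
    high_total = sum(table.high)
    if low_total == 0 or high_total == 0:
        raise ValueError("agreement table has an empty stratum")
    low_agree = table.low[1]       # reviewer said not-human
    high_agree = table.high[0]     # reviewer said human
    return AgreementStats(
        low_pct=100.0 * low_agree / low_total,
        high_pct=100.0 * high_agree / high_total,
        overall_pct=100.0 * (low_agree + high_agree) / (low_total + high_total),
    )
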