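"""Linear margin classifier and margin-to-probability calibration.

The classifier is an L2-regularized linear SVM (liblinear backend via
scikit-learn), as is standard for sparse bag-of-n-grams text problems.
Its signed margin distances are mapped to probabilities by a monotone
calibration map fitted on *out-of-fold* margins: the SVM is first fit
on 80% of the training data, margins are computed on the held-out 20%,
the calibrator is fitted there, and the SVM is then refit on all the
data with the calibration map retained.  Two interchangeable
calibrators are provided — a Platt-style sigmoid and clipped isotonic
regression (the default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .corpus_io import CitationRecord, Corpus, StopwordList
from .features import (DesignMatrix, FeatureClass, Vocabulary,
                       build_vocabulary, vectorize)

logger = logging.getLogger(__name__)

_FORMAT_VERSION = "humtag-tagger/1"

#: Probabilities from the isotonic calibrator are clipped away from the
#: hard 0/1 boundary so that log-loss style uses remain finite.
CLIP_EPS = 1e-4


@dataclass
class LinearModel:
    """A linear decision function: margin(x) = w·x + b."""

    weights: np.ndarray
    bias: float
    c_param: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)


def train_linear_svm(X: DesignMatrix | sp.spmatrix,
                     y: Sequence[bool] | np.ndarray,
                     c_param: float = 1.0,
                     seed: int = 0,
                     max_iter: int = 5000,
                     tol: float = 1e-4) -> LinearModel:
    """Fit an L2-regularized linear SVM on a sparse design matrix.

    Both classes must be present.  Deterministic given fixed inputs and
    seed.  The loss is unweighted: the positive class is the majority
    (~65–70%) in the intended application, so no class weighting is
    applied.
    """
    Xm = X.X if isinstance(X, DesignMatrix) else X
    y = np.asarray(y, dtype=bool)
    if Xm.shape[0] == 0:
        raise ValueError("empty design matrix")
    if Xm.shape[0] != y.shape[0]:
        raise ValueError(f"X has {Xm.shape[0]} rows but y has {y.shape[0]} labels")
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    if c_param <= 0:
        raise ValueError("c_param must be positive")
    clf = LinearSVC(C=c_param, random_state=seed % (2 ** 31), tol=tol,
                    max_iter=max_iter)
    clf.fit(Xm, y.astype(int))
    return LinearModel(weights=clf.coef_.ravel().copy(),
                       bias=float(clf.intercept_[0]),
                       c_param=c_param)


def margin_scores(model: LinearModel,
                  X: DesignMatrix | sp.spmatrix) -> np.ndarray:
    """Signed margin distance per row; positive = predicted Humans side."""
    Xm = X.X if isinstance(X, DesignMatrix) else X
    if Xm.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"design matrix has {Xm.shape[1]} columns but model expects "
            f"{model.weights.shape[0]}")
    return np.asarray(Xm @ model.weights).ravel() + model.bias


@dataclass
class CalibrationMap:
    """Monotone non-decreasing map from real margins to [0, 1].

    ``method`` is "isotonic" (knots ``x``/``y``, linear interpolation,
    clipped outside the fitted range and to [CLIP_EPS, 1-CLIP_EPS]) or
    "sigmoid" (p = 1/(1+exp(-(a·m + b)))).  Prediction is implemented
    directly on the stored parameters so a saved map reproduces
    bit-identical probabilities after reloading.
    """

    method: str
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    a: float | None = None
    b: float | None = None

    def __call__(self, margins) -> np.ndarray:
        return calibrate(self, margins)


def fit_calibration(margins: Sequence[float] | np.ndarray,
                    labels: Sequence[bool] | np.ndarray,
                    method: str = "isotonic") -> CalibrationMap:
    """Fit a monotone margin-to-probability map.

    Must be fitted on margins from data the SVM was *not* fit on,
    otherwise the probabilities are optimistic.
    """
    margins = np.asarray(margins, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if margins.shape[0] != labels.shape[0]:
        raise ValueError("margins and labels differ in length")
    if labels.all() or not labels.any():
        raise ValueError("calibration labels contain a single class")
    if not np.isfinite(margins).all():
        raise ValueError("margins must be finite")

    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(margins, labels.astype(np.float64))
        x = np.asarray(iso.X_thresholds_, dtype=np.float64)
        y = np.clip(np.asarray(iso.y_thresholds_, dtype=np.float64),
                    CLIP_EPS, 1.0 - CLIP_EPS)
        return CalibrationMap(method="isotonic", x=x, y=y)
    if method == "sigmoid":
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
        lr.fit(margins.reshape(-1, 1), labels.astype(int))
        return CalibrationMap(method="sigmoid",
                              a=float(lr.coef_[0, 0]),
                              b=float(lr.intercept_[0]))
    raise ValueError(f"unknown calibration method: {method!r}")


def calibrate(cmap: CalibrationMap, margins) -> np.ndarray | float:
    """Apply a calibration map; non-decreasing, always in [0, 1]."""
    m = np.asarray(margins, dtype=np.float64)
    scalar = m.ndim == 0
    m = np.atleast_1d(m)
    if cmap.method == "isotonic":
        if len(cmap.x) == 1:
            p = np.full_like(m, cmap.y[0])
        else:
            p = np.interp(m, cmap.x, cmap.y)
    elif cmap.method == "sigmoid":
        from scipy.special import expit
        p = expit(cmap.a * m + cmap.b)
    else:
        raise ValueError(f"unknown calibration method: {cmap.method!r}")
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


@dataclass
class TaggerConfig:
    """Training configuration.

    c_param: SVM regularization constant (default 1.0).
    min_df: minimum document frequency for token features (default 2).
    calibrator: "isotonic" or "sigmoid".
    calibration_fraction: held-out fraction for calibration fitting.
    """

    c_param: float = 1.0
    min_df: int = 2
    calibrator: str = "isotonic"
    calibration_fraction: float = 0.2
    seed: int = 0
    max_iter: int = 5000
    tol: float = 1e-4
    stopwords: StopwordList | None = None


@dataclass
class Tagger:
    """End-to-end citation tagger: feature classes, vocabulary, linear
    model, calibration map, and numeric-column standardization.

    Maps a citation to the probability that it should be indexed as a
    human-related study.  Predictions are a pure function of
    title/abstract/authors/journal/pagination — MeSH fields are never
    consulted.
    """

    classes: frozenset[FeatureClass]
    vocabulary: Vocabulary
    model: LinearModel
    calibration: CalibrationMap
    standardization: dict[int, tuple[float, float]]
    stopwords: StopwordList | None = None
    metadata: dict = field(default_factory=dict)

    # -- scoring ----------------------------------------------------------
    def margins(self, corpus: Corpus | Sequence[CitationRecord]) -> np.ndarray:
        dm = vectorize(corpus, self.vocabulary, self.stopwords)
        X = apply_standardization(dm.X, self.standardization)
        return margin_scores(self.model, X)

    def tag_corpus(self, corpus: Corpus | Sequence[CitationRecord]) -> np.ndarray:
        """Probability per record, in corpus order."""
        return calibrate(self.calibration, self.margins(corpus))

    def tag(self, record: CitationRecord) -> float:
        """Probability in [0, 1] that one citation is human-related."""
        return float(self.tag_corpus([record])[0])


def apply_standardization(X: sp.csr_matrix,
                          stats: dict[int, tuple[float, float]]) -> sp.csr_matrix:
    """Z-score the numeric columns of a sparse matrix with stored stats.

    Only the few numeric columns densify; token columns stay sparse.
    """
    if not stats:
        return X
    X = X.tocsc(copy=True).tolil()
    n = X.shape[0]
    for col, (mean, sd) in stats.items():
        vals = np.zeros(n)
        colmat = X[:, col].toarray().ravel()
        vals = (colmat - mean) / (sd if sd > 0 else 1.0)
        X[:, col] = vals.reshape(-1, 1)
    return X.tocsr()


def _standardization_stats(X: sp.csr_matrix,
                           numeric_cols: Iterable[int]) -> dict[int, tuple[float, float]]:
    stats = {}
    for col in numeric_cols:
        vals = np.asarray(X[:, col].todense()).ravel()
        stats[col] = (float(vals.mean()), float(vals.std()))
    return stats


def _stratified_split(y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, test) with the test set stratified by label."""
    test_idx = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(len(idx) * test_fraction)))
        test_idx.append(idx[:k])
    test = np.sort(np.concatenate(test_idx))
    mask = np.ones(len(y), dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


def train_tagger(corpus: Corpus | Sequence[CitationRecord],
                 classes: Iterable[FeatureClass],
                 config: TaggerConfig | None = None) -> Tagger:
    """Train the full pipeline on the labeled records of a corpus.

    Builds the vocabulary, vectorizes, standardizes numeric columns,
    fits the SVM on an internal 80% split, calibrates on the held-out
    20% margins, then refits the SVM on 100% of the data.
    Deterministic under a fixed config seed.
    """
    config = config or TaggerConfig()
    classes = frozenset(classes)
    records = [r for r in corpus if r.label is not None]
    y = np.array([r.label for r in records], dtype=bool)
    if len(records) == 0:
        raise ValueError("corpus has no labeled records")
    if (y.sum() < 2) or ((~y).sum() < 2):
        raise ValueError("need at least 2 labeled records per class")

    vocab = build_vocabulary(records, classes, min_df=config.min_df,
                             stopwords=config.stopwords)
    dm = vectorize(records, vocab, config.stopwords)
    stats = _standardization_stats(dm.X, vocab.numeric_columns())
    X = apply_standardization(dm.X, stats)

    rng = np.random.default_rng(config.seed)
    train_idx, cal_idx = _stratified_split(y, config.calibration_fraction, rng)
    if y[train_idx].all() or not y[train_idx].any():
        raise ValueError("internal calibration split left a single-class "
                         "training set; corpus too small or too imbalanced")

    svm = train_linear_svm(X[train_idx], y[train_idx], c_param=config.c_param,
                           seed=config.seed, max_iter=config.max_iter,
                           tol=config.tol)
    cal_margins = margin_scores(svm, X[cal_idx])
    cmap = fit_calibration(cal_margins, y[cal_idx], method=config.calibrator)

    final = train_linear_svm(X, y, c_param=config.c_param, seed=config.seed,
                             max_iter=config.max_iter, tol=config.tol)

    provenance = corpus.provenance if isinstance(corpus, Corpus) else ""
    return Tagger(
        classes=classes,
        vocabulary=vocab,
        model=final,
        calibration=cmap,
        standardization=stats,
        stopwords=config.stopwords,
        metadata={
            "format_version": _FORMAT_VERSION,
            "seed": config.seed,
            "c_param": config.c_param,
            "min_df": config.min_df,
            "calibrator": config.calibrator,
            "n_train": len(records),
            "corpus": provenance,
        },
    )


# ---------------------------------------------------------------------------
# Serialization (single JSON archive; text-only, timestamp-free so reruns
# with the same seed write identical bytes)
# ---------------------------------------------------------------------------

def save_tagger(tagger: Tagger, path: str | Path | IO) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "classes": sorted(fc.value for fc in tagger.classes),
        "vocabulary": {tok: idx for tok, idx in tagger.vocabulary.entries.items()},
        "weights": tagger.model.weights.tolist(),
        "bias": tagger.model.bias,
        "c_param": tagger.model.c_param,
        "calibration": {
            "method": tagger.calibration.method,
            "x": None if tagger.calibration.x is None else tagger.calibration.x.tolist(),
            "y": None if tagger.calibration.y is None else tagger.calibration.y.tolist(),
            "a": tagger.calibration.a,
            "b": tagger.calibration.b,
        },
        "standardization": {str(k): list(v) for k, v in tagger.standardization.items()},
        "stopwords": (sorted(tagger.stopwords.tokens)
                      if tagger.stopwords is not None else None),
        "metadata": tagger.metadata,
    }
    text = json.dumps(payload, ensure_ascii=False, sort_keys=True)
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def load_tagger(path: str | Path | IO) -> Tagger:
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt tagger archive: {exc}") from exc
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"tagger archive version {version!r} is not "
                         f"supported (expected {_FORMAT_VERSION!r})")
    classes = frozenset(FeatureClass(c) for c in payload["classes"])
    vocab = Vocabulary(entries=payload["vocabulary"], classes=classes)
    cal = payload["calibration"]
    cmap = CalibrationMap(
        method=cal["method"],
        x=None if cal["x"] is None else np.asarray(cal["x"], dtype=np.float64),
        y=None if cal["y"] is None else np.asarray(cal["y"], dtype=np.float64),
        a=cal["a"], b=cal["b"],
    )
    stop = payload.get("stopwords")
    return Tagger(
        classes=classes,
        vocabulary=vocab,
        model=LinearModel(weights=np.asarray(payload["weights"]),
                          bias=float(payload["bias"]),
                          c_param=float(payload["c_param"])),
        calibration=cmap,
        standardization={int(k): (float(v[0]), float(v[1]))
                         for k, v in payload["standardization"].items()},
        stopwords=StopwordList(frozenset(stop)) if stop is not None else None,
        metadata=payload.get("metadata", {}),
    )
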