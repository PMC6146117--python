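"""Forward selection of feature classes under 5x2 cross-validation.

Feature classes are added greedily: at each stage every remaining
class is evaluated in combination with the classes already included,
using five independent stratified 50/50 splits of the labeled corpus
(ten train/test fits per evaluation, metrics averaged).  The class
with the largest AUC improvement wins; with no AUC change, the
largest MCC improvement breaks the tie.  Neither metric is ever
allowed to decrease; selection stops when no admissible class
improves either metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Corpus
from .features import FeatureClass
from .metrics import auc, binarize, binary_metrics
from .model import TaggerConfig, train_tagger

logger = logging.getLogger(__name__)

#: Metric-comparison tolerance: differences within EPS count as
#: "no change", absorbing floating-point jitter.
DEFAULT_EPS = 1e-4


@dataclass(frozen=True)
class MetricPair:
    """(AUC, MCC) — the two metrics driving forward selection."""

    auc: float
    mcc: float


@dataclass(frozen=True)
class FoldPlan:
    """Five independent stratified 50/50 partitions of the record ids."""

    iterations: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int


def make_5x2_folds(corpus: Corpus, seed: int) -> FoldPlan:
    """Five random stratified two-way splits, reproducible from seed.

    Each iteration partitions the labeled ids into two halves whose
    label prevalence matches the corpus within one record.
    """
    labeled = [r for r in corpus if r.label is not None]
    pos = [r.id for r in labeled if r.label]
    neg = [r.id for r in labeled if not r.label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("corpus too small for stratified 50/50 halves "
                         "(need >= 2 labeled records per class)")
    rng = np.random.default_rng(seed)
    iterations = []
    for _ in range(5):
        half_a: list[str] = []
        half_b: list[str] = []
        for ids in (pos, neg):
            perm = rng.permutation(ids)
            half = len(perm) // 2
            half_a.extend(perm[:half])
            half_b.extend(perm[half:])
        iterations.append((tuple(sorted(half_a)), tuple(sorted(half_b))))
    return FoldPlan(iterations=tuple(iterations), seed=seed)


def cv_evaluate(corpus: Corpus,
                classes: Iterable[FeatureClass],
                plan: FoldPlan,
                config: TaggerConfig | None = None) -> MetricPair:
    """Mean (AUC, MCC) over the ten train/test arrangements of a plan.

    For each of the five iterations a tagger is trained on one half
    and scored on the other, in both directions; AUC and MCC (at the
    0.50 threshold) are computed per test half and averaged.
    """
    classes = frozenset(classes)
    if not classes:
        raise ValueError("empty feature-class set")
    config = config or TaggerConfig()
    aucs, mccs = [], []
    for it, (half_a, half_b) in enumerate(plan.iterations):
        for train_ids, test_ids in ((half_a, half_b), (half_b, half_a)):
            train = corpus.subset(train_ids)
            test = corpus.subset(test_ids)
            tagger = train_tagger(train, classes, config)
            labels = np.array([r.label for r in test if r.label is not None],
                              dtype=bool)
            scores = tagger.tag_corpus([r for r in test if r.label is not None])
            aucs.append(auc(scores, labels))
            mccs.append(binary_metrics(binarize(scores, labels)).mcc)
    return MetricPair(auc=float(np.mean(aucs)), mcc=float(np.mean(mccs)))


def improvement_rule(current: MetricPair,
                     candidates: Sequence[tuple[FeatureClass, MetricPair]],
                     eps: float = DEFAULT_EPS) -> FeatureClass | None:
    """The AUC-then-MCC greedy choice with a no-decrease constraint.

    Candidates that would decrease either AUC or MCC (beyond eps) are
    inadmissible.  Among the rest, the largest AUC gain wins; if no
    candidate changes AUC, the largest MCC gain wins.  Returns None
    when nothing improves either metric — selection stops.  Ties after
    both rules break by feature-class enumeration order.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    order = {fc: i for i, fc in enumerate(FeatureClass)}
    admissible = [(fc, m) for fc, m in candidates
                  if m.auc >= current.auc - eps and m.mcc >= current.mcc - eps]
    if not admissible:
        return None
    best_dauc = max(m.auc - current.auc for _, m in admissible)
    if best_dauc > eps:
        top = [(fc, m) for fc, m in admissible if m.auc - current.auc >= best_dauc - eps]
        top.sort(key=lambda cm: (-(cm[1].mcc - current.mcc), order[cm[0]]))
        return top[0][0]
    best_dmcc = max(m.mcc - current.mcc for _, m in admissible)
    if best_dmcc > eps:
        top = [(fc, m) for fc, m in admissible if m.mcc - current.mcc >= best_dmcc - eps]
        top.sort(key=lambda cm: order[cm[0]])
        return top[0][0]
    return None


@dataclass
class SelectionTrace:
    """Record of a forward-selection run: one stage per included class."""

    stages: list[tuple[FeatureClass, MetricPair]] = field(default_factory=list)
    rejected: list[FeatureClass] = field(default_factory=list)

    def selected(self) -> list[FeatureClass]:
        return [fc for fc, _ in self.stages]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("stage\tfeature\tauc\tmcc\n")
            for i, (fc, m) in enumerate(self.stages, start=1):
                fh.write(f"{i}\t{fc.value}\t{m.auc:.6f}\t{m.mcc:.6f}\n")


def forward_select(corpus: Corpus,
                   candidate_classes: Sequence[FeatureClass],
                   seed: int = 0,
                   config: TaggerConfig | None = None,
                   eps: float = DEFAULT_EPS) -> SelectionTrace:
    """Greedy forward selection over feature classes.

    One fold plan is drawn per run and shared by every candidate
    evaluation (paired comparisons).  The trace's AUC and MCC columns
    are non-decreasing by construction.  Deterministic under seed.
    """
    candidates = list(dict.fromkeys(candidate_classes))
    trace = SelectionTrace()
    if not candidates:
        return trace
    config = config or TaggerConfig()
    plan = make_5x2_folds(corpus, seed)

    included: list[FeatureClass] = []
    current = MetricPair(auc=0.5, mcc=0.0)  # chance-level baseline
    while candidates:
        evaluated = []
        for fc in candidates:
            m = cv_evaluate(corpus, set(included) | {fc}, plan, config)
            evaluated.append((fc, m))
            logger.info("stage %d candidate %s: AUC=%.4f MCC=%.4f",
                        len(included) + 1, fc.value, m.auc, m.mcc)
        chosen = improvement_rule(current, evaluated, eps)
        if chosen is None:
            break
        current = dict(evaluated)[chosen]
        included.append(chosen)
        candidates.remove(chosen)
        trace.stages.append((chosen, current))
        logger.info("stage %d selected %s (AUC=%.4f MCC=%.4f)",
                    len(included), chosen.value, current.auc, current.mcc)
    trace.rejected = candidates
    return trace
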