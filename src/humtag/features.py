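"""Feature classes: converting citations into sparse design matrices.

Features are organised into *feature classes* — families of related
features produced by one extractor (all title bigrams are one class,
all abstract unigrams another).  The feature class is the unit of
forward selection.  Text classes are bag-of-n-grams over tokens split
on whitespace and punctuation, lower-cased, stop words removed, no
stemming.  Numeric classes (word/punctuation/numeric-token counts,
author count, page count) contribute one fixed column per quantity.
"""

from __future__ import annotations

import logging
import re
import string
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus_io import CitationRecord, Corpus, StopwordList

logger = logging.getLogger(__name__)

#: Characters treated as punctuation for token splitting and punct counts.
PUNCTUATION = set(string.punctuation)

_SPLIT_RE = re.compile(r"[\s" + re.escape(string.punctuation) + r"]+")


class FeatureClass(Enum):
    """The fixed, ordered enumeration of feature classes.

    Declaration order is the deterministic tie-break order used by
    forward selection.
    """

    TITLE_UNIGRAM = "TITLE_UNIGRAM"
    TITLE_BIGRAM = "TITLE_BIGRAM"
    TITLE_TRIGRAM = "TITLE_TRIGRAM"
    ABSTRACT_UNIGRAM = "ABSTRACT_UNIGRAM"
    ABSTRACT_BIGRAM = "ABSTRACT_BIGRAM"
    ABSTRACT_TRIGRAM = "ABSTRACT_TRIGRAM"
    TITLE_COUNTS = "TITLE_COUNTS"
    ABSTRACT_COUNTS = "ABSTRACT_COUNTS"
    AUTHOR_NAMES = "AUTHOR_NAMES"
    AUTHOR_COUNT = "AUTHOR_COUNT"
    JOURNAL_NAME = "JOURNAL_NAME"
    PAGE_COUNT = "PAGE_COUNT"


#: Classes whose columns hold raw numeric quantities (standardized at
#: training time) rather than token counts.
NUMERIC_CLASSES = frozenset({
    FeatureClass.TITLE_COUNTS,
    FeatureClass.ABSTRACT_COUNTS,
    FeatureClass.AUTHOR_COUNT,
    FeatureClass.PAGE_COUNT,
})

_COUNTS_SUBFIELDS = ("word_count", "punct_count", "numeric_count")

_NGRAM_ORDER = {
    FeatureClass.TITLE_UNIGRAM: 1,
    FeatureClass.TITLE_BIGRAM: 2,
    FeatureClass.TITLE_TRIGRAM: 3,
    FeatureClass.ABSTRACT_UNIGRAM: 1,
    FeatureClass.ABSTRACT_BIGRAM: 2,
    FeatureClass.ABSTRACT_TRIGRAM: 3,
}

_TITLE_NGRAMS = {FeatureClass.TITLE_UNIGRAM, FeatureClass.TITLE_BIGRAM,
                 FeatureClass.TITLE_TRIGRAM}


def tokenize(text: str | None, stopwords: StopwordList | None = None) -> list[str]:
    """Split on whitespace and punctuation, lower-case, drop stop words.

    No stemming.  Order is preserved; empty tokens are dropped.  Absent
    text is treated as empty.
    """
    if not text:
        return []
    tokens = [t for t in _SPLIT_RE.split(text.lower()) if t]
    if stopwords is not None:
        tokens = [t for t in tokens if t not in stopwords]
    return tokens


def ngrams(tokens: Sequence[str], n: int) -> Counter:
    """Contiguous n-token windows joined with '_', with multiplicities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(tokens) < n:
        return Counter()
    return Counter("_".join(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


@dataclass(frozen=True)
class CountFeatures:
    """Surface statistics of a text field; all zero for absent text."""

    word_count: int
    punct_count: int
    numeric_count: int


def count_features(text: str | None) -> CountFeatures:
    """Word / punctuation-symbol / numeric-term counts of a text field.

    Words are whitespace-delimited tokens (before punctuation
    splitting); a numeric term is a word containing at least one digit.
    """
    if not text:
        return CountFeatures(0, 0, 0)
    words = text.split()
    punct = sum(1 for ch in text if ch in PUNCTUATION)
    numeric = sum(1 for w in words if any(c.isdigit() for c in w))
    return CountFeatures(len(words), punct, numeric)


_RANGE_RE = re.compile(r"(\d+)\s*-\s*(\d+)$")
_SINGLE_RE = re.compile(r"(\d+)$")
_ELECTRONIC_RE = re.compile(r"[eE]\d+$")


def page_count(pagination: str | None) -> int:
    """Page extent from a MEDLINE pagination string.

    Expands MEDLINE shorthand ("334-41" means 334–341, 8 pages
    inclusive); a single page number counts 1; electronic pagination
    ("e0123456") and unparseable strings count 0.
    """
    if not pagination:
        return 0
    s = pagination.strip()
    m = _RANGE_RE.fullmatch(s)
    if m:
        start_s, end_s = m.group(1), m.group(2)
        if len(end_s) < len(start_s):
            end_s = start_s[:len(start_s) - len(end_s)] + end_s
        start, end = int(start_s), int(end_s)
        if end < start:
            logger.warning("pagination %r has end before start; page count 0", pagination)
            return 0
        return end - start + 1
    if _SINGLE_RE.fullmatch(s):
        return 1
    if _ELECTRONIC_RE.fullmatch(s):
        return 0
    logger.warning("unparseable pagination %r; page count 0", pagination)
    return 0


def bibliographic_features(record: CitationRecord) -> Counter:
    """Class-qualified bibliographic features of one record.

    Author names become ``lastname_initials`` tokens (lower-cased,
    whitespace collapsed); author count, journal name, and page count
    contribute one feature each.
    """
    feats: Counter = Counter()
    for last, initials in record.authors:
        name = _collapse(last) + "_" + _collapse(initials)
        feats[f"{FeatureClass.AUTHOR_NAMES.value}:{name}"] += 1
    feats[f"{FeatureClass.AUTHOR_COUNT.value}:value"] = len(record.authors)
    if record.journal:
        feats[f"{FeatureClass.JOURNAL_NAME.value}:{record.journal.strip().lower()}"] = 1
    feats[f"{FeatureClass.PAGE_COUNT.value}:value"] = page_count(record.pagination)
    return feats


def _collapse(text: str) -> str:
    return re.sub(r"\s+", "_", text.strip().lower())


def record_features(record: CitationRecord,
                    classes: Iterable[FeatureClass],
                    stopwords: StopwordList | None = None) -> dict[str, float]:
    """All class-qualified features of one record, restricted to `classes`.

    Keys are ``CLASSNAME:token``; values are counts for token classes
    and raw quantities for numeric classes.  MeSH fields are never
    consulted — predictions must work for unindexed records.
    """
    classes = set(classes)
    feats: dict[str, float] = {}

    title_tokens = abstract_tokens = None
    if classes & _TITLE_NGRAMS:
        title_tokens = tokenize(record.title, stopwords)
    if classes & (set(_NGRAM_ORDER) - _TITLE_NGRAMS):
        abstract_tokens = tokenize(record.abstract, stopwords)

    for fc in classes:
        if fc in _NGRAM_ORDER:
            toks = title_tokens if fc in _TITLE_NGRAMS else abstract_tokens
            for tok, cnt in ngrams(toks, _NGRAM_ORDER[fc]).items():
                feats[f"{fc.value}:{tok}"] = float(cnt)
        elif fc is FeatureClass.TITLE_COUNTS or fc is FeatureClass.ABSTRACT_COUNTS:
            text = record.title if fc is FeatureClass.TITLE_COUNTS else record.abstract
            cf = count_features(text)
            for sub in _COUNTS_SUBFIELDS:
                feats[f"{fc.value}:{sub}"] = float(getattr(cf, sub))
        else:
            bib = bibliographic_features(record)
            prefix = fc.value + ":"
            for tok, cnt in bib.items():
                if tok.startswith(prefix):
                    feats[tok] = float(cnt)
    return feats


@dataclass(frozen=True)
class Vocabulary:
    """Mapping from class-qualified feature token to dense column index.

    Column order is deterministic: feature classes in enumeration
    order, tokens lexicographic within each class; numeric classes
    contribute their fixed columns regardless of document frequency.
    """

    entries: Mapping[str, int]
    classes: frozenset[FeatureClass]

    @property
    def n_columns(self) -> int:
        return len(self.entries)

    def numeric_columns(self) -> list[int]:
        """Column indices that hold raw numeric values (to standardize)."""
        numeric_prefixes = tuple(fc.value + ":" for fc in NUMERIC_CLASSES)
        return sorted(idx for tok, idx in self.entries.items()
                      if tok.startswith(numeric_prefixes))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, idx in sorted(self.entries.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Vocabulary":
        entries: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").rsplit("\t", 1)
                entries[tok] = int(idx)
        classes = frozenset(FeatureClass(tok.split(":", 1)[0]) for tok in entries)
        return cls(entries=entries, classes=classes)


def build_vocabulary(corpus: Corpus | Sequence[CitationRecord],
                     classes: Iterable[FeatureClass],
                     min_df: int = 2,
                     stopwords: StopwordList | None = None) -> Vocabulary:
    """Learn the feature space of the requested classes from a corpus.

    Token features must appear in at least ``min_df`` distinct records;
    numeric quantities always get their fixed column.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("empty feature-class set")
    records = list(corpus)
    if not records:
        raise ValueError("empty corpus")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")

    df: Counter = Counter()
    for rec in records:
        df.update(set(record_features(rec, classes, stopwords)))

    entries: dict[str, int] = {}
    for fc in FeatureClass:
        if fc not in classes:
            continue
        prefix = fc.value + ":"
        if fc in NUMERIC_CLASSES:
            if fc in (FeatureClass.TITLE_COUNTS, FeatureClass.ABSTRACT_COUNTS):
                fixed = [prefix + sub for sub in _COUNTS_SUBFIELDS]
            else:
                fixed = [prefix + "value"]
            for tok in fixed:
                entries[tok] = len(entries)
        else:
            kept = sorted(t for t, n in df.items()
                          if t.startswith(prefix) and n >= min_df)
            for tok in kept:
                entries[tok] = len(entries)
    return Vocabulary(entries=entries, classes=frozenset(classes))


@dataclass
class DesignMatrix:
    """Sparse feature matrix aligned with a corpus ordering."""

    X: sp.csr_matrix
    vocabulary: Vocabulary
    ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def write_mtx(self, path: str | Path) -> None:
        """Export as MatrixMarket plus a row-id sidecar (path + '.rows')."""
        from scipy.io import mmwrite
        mmwrite(str(path), self.X)
        with open(str(path) + ".rows", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.ids) + "\n")


def vectorize(corpus: Corpus | Sequence[CitationRecord],
              vocabulary: Vocabulary,
              stopwords: StopwordList | None = None) -> DesignMatrix:
    """Encode records as sparse rows over a closed vocabulary.

    Tokens outside the vocabulary are ignored; row order follows corpus
    order; each row is a pure function of its own record.
    """
    records = list(corpus)
    entries = vocabulary.entries
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for rec in records:
        feats = record_features(rec, vocabulary.classes, stopwords)
        cols = sorted((entries[t], v) for t, v in feats.items() if t in entries)
        indices.extend(c for c, _ in cols)
        data.extend(v for _, v in cols)
        indptr.append(len(indices))
    X = sp.csr_matrix((np.asarray(data, dtype=np.float64),
                       np.asarray(indices, dtype=np.int32),
                       np.asarray(indptr, dtype=np.int32)),
                      shape=(len(records), vocabulary.n_columns))
    return DesignMatrix(X=X, vocabulary=vocabulary, ids=[r.id for r in records])
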