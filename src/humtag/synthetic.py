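"""Synthetic citation corpora with known generative posteriors.

The generator emulates a labeled bibliographic corpus: a Bernoulli
label (human-related or not) with controllable prevalence, and
class-conditional multinomial token distributions for the title and
abstract plus a class-skewed categorical journal.  A fraction of each
field's vocabulary is *informative*: informative tokens are created
in +/- pairs sharing the same base probability mass, with their
class-conditional log-odds shifted by +separation and -separation
respectively.  Because each pair contributes equal mass to both
class normalizers, the normalizers cancel and every informative
token's log-likelihood ratio is exactly +/-separation — so the exact
Bayes posterior of every generated record is available in closed
form, and with it the Bayes-optimal AUC ceiling that no tagger can
beat.

Author names and field lengths are label-independent by construction
(they carry no signal).  The generator makes no attempt to mimic real
English text or MeSH co-assignment structure; adjacent token draws
are independent, so n-grams beyond unigrams carry no extra signal.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .corpus_io import CitationRecord, Corpus
from .metrics import auc


def _word(prefix: str, i: int) -> str:
    """Letters-only token name (survives tokenization, never a stop word)."""
    letters = string.ascii_lowercase
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = letters[r] + s
    return prefix + s


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for a synthetic corpus.

    prevalence mirrors the application domain, where roughly 65% of
    indexed records are human-related.  separation is the log-odds
    shift of informative tokens (per occurrence); title/abstract/
    journal separations default to it.  Lengths are Poisson means.
    """

    n_records: int = 2000
    prevalence: float = 0.65
    title_vocab: int = 120
    abstract_vocab: int = 300
    separation: float = 2.0
    informative_fraction: float = 0.2
    title_separation: float | None = None
    abstract_separation: float | None = None
    journal_separation: float = 1.0
    title_length_mean: float = 8.0
    abstract_length_mean: float = 60.0
    n_journals: int = 200
    n_authors_pool: int = 500
    missing_abstract_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "informative_fraction", "missing_abstract_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_records < 1:
            raise ValueError(f"n_records must be >= 1, got {self.n_records}")
        for name in ("separation", "journal_separation"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def medline_like(n_records: int = 20000, seed: int = 0,
                 **overrides) -> GeneratorParams:
    """The default preset: 65% prevalence, 10% missing abstracts,
    200-journal pool, high token separation."""
    return GeneratorParams(n_records=n_records, seed=seed, **overrides)


@dataclass
class _FieldModel:
    """Class-conditional multinomial over one field's vocabulary."""

    names: list[str]
    delta: np.ndarray       # exact per-token log-likelihood ratio
    p_pos: np.ndarray
    p_neg: np.ndarray
    index: dict[str, int]


def _build_field(prefix: str, vocab: int, informative_fraction: float,
                 separation: float, rng: np.random.Generator) -> _FieldModel:
    # Informative tokens come in (+, -) pairs with equal base mass so the
    # class normalizers cancel and delta is exactly +/-separation.
    k = int(round(vocab * informative_fraction))
    k -= k % 2
    delta = np.zeros(vocab)
    delta[0:k:2] = separation
    delta[1:k:2] = -separation
    base = rng.dirichlet(np.full(vocab, 5.0))
    for i in range(0, k, 2):
        m = (base[i] + base[i + 1]) / 2.0
        base[i] = base[i + 1] = m
    w_pos = base * np.exp(delta / 2.0)
    w_neg = base * np.exp(-delta / 2.0)
    # normalizers are equal by the pairing; normalize anyway for safety
    p_pos = w_pos / w_pos.sum()
    p_neg = w_neg / w_neg.sum()
    names = [_word(prefix, i) for i in range(vocab)]
    return _FieldModel(names=names, delta=delta, p_pos=p_pos, p_neg=p_neg,
                       index={n: i for i, n in enumerate(names)})


@dataclass
class GeneratedCorpus:
    """A synthetic corpus plus the exact posterior of each record."""

    corpus: Corpus
    params: GeneratorParams
    posterior: np.ndarray

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.corpus], dtype=bool)

    def write_posteriors(self, path: str | Path) -> None:
        """Sidecar TSV of (id, true posterior)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tposterior\n")
            for rec, p in zip(self.corpus, self.posterior):
                fh.write(f"{rec.id}\t{p:.6f}\n")


class SyntheticModel:
    """The deterministic generative model implied by a parameter set.

    Reconstructing the model from the same params (including seed)
    yields the same token tables, so posteriors of previously
    generated records can be recomputed exactly.
    """

    def __init__(self, params: GeneratorParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        t_sep = (params.title_separation if params.title_separation is not None
                 else params.separation)
        a_sep = (params.abstract_separation if params.abstract_separation is not None
                 else params.separation)
        self.title = _build_field("t", params.title_vocab,
                                  params.informative_fraction, t_sep, rng)
        self.abstract = _build_field("a", params.abstract_vocab,
                                     params.informative_fraction, a_sep, rng)
        self.journal = _build_field("journal", params.n_journals,
                                    1.0 if params.journal_separation > 0 else 0.0,
                                    params.journal_separation, rng)
        self.author_pool = [(_word("au", i), _word("", rng.integers(0, 26)).upper())
                            for i in range(params.n_authors_pool)]
        self._record_rng = rng

    # -- generation -------------------------------------------------------
    def generate(self) -> GeneratedCorpus:
        p = self.params
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
        labels = rng.random(p.n_records) < p.prevalence
        records, posteriors = [], []
        for i in range(p.n_records):
            rec, post = self._one_record(i, bool(labels[i]), rng)
            records.append(rec)
            posteriors.append(post)
        corpus = Corpus(records, provenance=f"synthetic(seed={p.seed}, n={p.n_records})")
        return GeneratedCorpus(corpus=corpus, params=p,
                               posterior=np.asarray(posteriors))

    def _one_record(self, i: int, label: bool,
                    rng: np.random.Generator) -> tuple[CitationRecord, float]:
        p = self.params
        n_title = 1 + rng.poisson(p.title_length_mean - 1)
        title_ix = rng.choice(p.title_vocab, size=n_title,
                              p=self.title.p_pos if label else self.title.p_neg)
        title = " ".join(self.title.names[j] for j in title_ix)

        abstract = None
        abstract_ix = np.empty(0, dtype=int)
        if rng.random() >= p.missing_abstract_rate:
            n_abs = 1 + rng.poisson(p.abstract_length_mean - 1)
            abstract_ix = rng.choice(p.abstract_vocab, size=n_abs,
                                     p=self.abstract.p_pos if label
                                     else self.abstract.p_neg)
            abstract = " ".join(self.abstract.names[j] for j in abstract_ix)

        j_ix = rng.choice(p.n_journals,
                          p=self.journal.p_pos if label else self.journal.p_neg)
        journal = self.journal.names[j_ix]

        n_auth = 1 + rng.poisson(2)
        auth_ix = rng.integers(0, p.n_authors_pool, size=n_auth)
        authors = tuple(self.author_pool[a] for a in auth_ix)

        start = int(rng.integers(1, 2000))
        extent = int(rng.integers(1, 15))
        end = start + extent - 1
        end_s = str(end)
        start_s = str(start)
        if len(end_s) == len(start_s):  # MEDLINE shorthand drops shared prefix
            k = 0
            while k < len(start_s) - 1 and start_s[k] == end_s[k]:
                k += 1
            end_s = end_s[k:]
        pagination = f"{start_s}-{end_s}"

        logit_post = (logit(p.prevalence)
                      + self.title.delta[title_ix].sum()
                      + self.abstract.delta[abstract_ix].sum()
                      + self.journal.delta[j_ix])
        rec = CitationRecord(
            id=f"syn-{p.seed}-{i:06d}",
            title=title, abstract=abstract, authors=authors,
            journal=journal, pagination=pagination, year=2015,
            mesh_terms=("Humans", "Female") if label else ("Mice",),
            label=label,
        )
        return rec, float(expit(logit_post))

    # -- posterior recomputation -----------------------------------------
    def posterior_for(self, record: CitationRecord) -> float:
        """Exact Bayes posterior P(label | fields) of a generated record.

        Raises for records whose tokens are not in this model's
        vocabulary (foreign records).
        """
        p = self.params
        lp = logit(p.prevalence)
        for tok in record.title.split():
            if tok not in self.title.index:
                raise ValueError(f"foreign title token {tok!r}")
            lp += self.title.delta[self.title.index[tok]]
        if record.abstract is not None:
            for tok in record.abstract.split():
                if tok not in self.abstract.index:
                    raise ValueError(f"foreign abstract token {tok!r}")
                lp += self.abstract.delta[self.abstract.index[tok]]
        if record.journal not in self.journal.index:
            raise ValueError(f"foreign journal {record.journal!r}")
        lp += self.journal.delta[self.journal.index[record.journal]]
        return float(expit(lp))


def generate(params: GeneratorParams) -> GeneratedCorpus:
    """Generate a labeled synthetic corpus; deterministic under seed."""
    return SyntheticModel(params).generate()


def true_posterior(record: CitationRecord, params: GeneratorParams) -> float:
    """Recompute the exact generative posterior of a generated record."""
    return SyntheticModel(params).posterior_for(record)


def bayes_auc_estimate(gen: GeneratedCorpus) -> float:
    """AUC of the true posteriors — the ceiling for any tagger here."""
    post = gen.posterior
    labels = gen.labels()
    if len(set(np.round(post, 12))) == 1:
        return 0.5  # uninformative limit: all posteriors equal
    return auc(post, labels)
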