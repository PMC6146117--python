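# Methods

## Model

A citation is represented as a sparse non-negative feature vector `x`
assembled from *feature classes* — families of features produced by one
extractor. Text classes are bags of n-grams: the title and abstract are
tokenized by splitting on whitespace and any ASCII punctuation
character, lower-cased, stop words removed (a bundled snapshot of a
standard English stop-word list; any user list is accepted), and not
stemmed. N-grams are contiguous windows over the post-stop-word token
sequence, joined with `_`, counted with multiplicity; they never cross
the title/abstract boundary but do cross sentence boundaries (no
sentence segmentation is performed). Count classes contribute one fixed
column per quantity: words (whitespace tokens before punctuation
splitting), punctuation symbols (ASCII set), and numeric terms
(whitespace tokens containing at least one digit). Bibliographic
classes contribute author-name tokens (`lastname_initials`,
lower-cased, whitespace collapsed), the author count, the journal name
as a single categorical token, and the page count.

Page count expands the standard bibliographic shorthand: `334-41` means
pages 334–341, an extent of 8; a bare page number counts 1; electronic
pagination (`e0123456`) and unparseable strings count 0. This parsing
rule is a documented package choice — the field convention leaves the
computation of "page count" open.

The classifier is an L2-regularized linear SVM (liblinear backend via
scikit-learn's `LinearSVC`), the standard choice for large sparse text
problems; regularization constant `C = 1.0` by default, unweighted loss
(the positive class is the majority in the intended application, so
re-weighting is unnecessary). N-gram features enter as raw counts —
presence/absence would also work, but counts preserve information and a
linear model can learn either. Numeric columns are z-scored with
training-set mean/sd (stored in the tagger) so their magnitudes are
commensurate with count features for a margin classifier.

## Calibration

The SVM's signed margin is mapped to a probability by a monotone
calibration map fitted on **out-of-fold** margins: the SVM is fit on a
stratified 80% of the training records, margins are computed on the
held-out 20%, the calibrator is fitted there, and the SVM is refit on
100% of the data with the calibration map retained. Fitting the
calibrator on in-fold margins would make the probabilities optimistic.

Two calibrator families sit behind one interface:

- **isotonic** (default): isotonic regression of the 0/1 labels on the
  margins, predicted by linear interpolation between the fitted knots,
  clipped to `[1e-4, 1 - 1e-4]` so no probability is exactly 0 or 1.
  Non-parametric, monotone by construction.
- **sigmoid**: a Platt-style logistic fit `p = σ(a·m + b)` on the
  margins (unpenalized logistic regression; no target smoothing).

Both are standard monotone margin→probability maps; the test surface
checks calibration *quality*, not a parametric family. Prediction is
implemented directly on the stored knots/coefficients, so a saved
tagger reproduces bit-identical probabilities after reloading.

## Reference labels

The reference standard is derived from the MeSH descriptor list: a
record is positive iff its descriptors contain the `Humans` heading
(exact string after whitespace trim; the unique identifier `D006801` is
accepted as an alias). Records with no MeSH at all are retained but
**unlabeled** — absence of indexing is never treated as a negative —
and are skipped by training and evaluation. Citation tables may also
carry labels directly (used by the synthetic generator). Predictions
are a pure function of title/abstract/authors/journal/pagination: MeSH
fields are never consulted at scoring time, so the tagger applies to
unindexed and non-MEDLINE records.

## Forward selection

Candidate feature classes are added greedily. One fold plan — five
independent stratified 50/50 partitions of the labeled records — is
drawn per run and shared by every candidate evaluation, so comparisons
are paired and lower-variance. Evaluating a candidate set means ten
fits (each half trains a full tagger, including its internal
calibration split; the other half is scored), with AUC and MCC (at the
0.50 threshold) computed per test half and **averaged** over the ten
(averaging rather than pooling predictions is a documented choice).
The class with the largest AUC gain is added; if no candidate changes
AUC, the largest MCC gain wins; a candidate that would decrease either
metric is inadmissible; remaining ties break by the fixed feature-class
enumeration order. Metric comparisons use a tolerance `eps = 1e-4` —
"no change" is otherwise numerically undefined — chosen to absorb
floating-point jitter without masking real gains. Selection stops when
no admissible candidate improves either metric.

Per-token statistical selection (χ², information gain) is deliberately
not implemented: greedy selection over whole classes retains the many
weakly-predictive features whose combined contribution individual
filtering destroys.

## Metrics

AUC is computed in the Mann–Whitney rank formulation with ties counted
½ (equivalent to the probability that a random positive outscores a
random negative). MCC returns 0 when any confusion-table marginal is
zero; thresholding uses `score ≥ 0.50` as positive (a side must be
picked for the boundary). The calibration curve uses fixed-width bins
(default 0.05, giving 20 bins) partitioning [0, 1], retaining empty
bins with n = 0. The adjusted R² of the reliability curve is a simple
linear regression of observed positive proportions on mean predicted
scores over populated bins (n = bins, one predictor); an optional
minimum bin count restricts the fit to well-populated bins, because a
bin holding a handful of records has a 0-or-1 observed proportion that
carries no calibration information — small-corpus reliability analyses
should raise it (the acceptance script uses 50).

Agreement statistics summarize a blinded manual review of *extreme
disagreements*: index-positive records scored < 0.01 (model predicts
NOT_HUMAN; reviewer "not human" verdicts agree) and index-negative
records scored > 0.99 (model predicts HUMAN; "human" verdicts agree);
UNCERTAIN verdicts count as non-matches. The review itself is human
work; the package provides the sampling (seeded, up to 100 per stratum
by default) and the arithmetic.

## Synthetic corpus generator

The generator emulates a labeled bibliographic corpus with a known
generative model. Labels are Bernoulli(prevalence), default 0.65 —
the approximate fraction of indexed biomedical citations that are
human-related. Title and abstract tokens are drawn i.i.d. from
class-conditional multinomials over letters-only synthetic vocabularies
(default 120 title / 300 abstract types); field lengths are
Poisson-distributed (means 8 and 60) independently of the label;
abstracts are missing completely at random (rate 0.1); journals come
from a class-skewed 200-journal categorical; author names and counts
are label-independent.

An `informative_fraction` (default 0.2) of each field's vocabulary is
informative: informative tokens are created in (+, −) pairs whose two
members share the same base probability mass, with class-conditional
log-odds shifted by `+separation` and `−separation` (default 2.0 —
well-separated classes, the regime the tagger is intended for).
Because each pair contributes equal mass to both class normalizers,
the normalizers cancel and every informative token's log-likelihood
ratio is **exactly** ±separation. The exact posterior of any generated
record is therefore available in closed form:

    logit P(y=1 | record) = logit(prevalence) + Σ_tokens δ(token) + δ(journal)

and the AUC of these posteriors is the Bayes ceiling no classifier can
beat. Per-field separation overrides (`title_separation`,
`abstract_separation`, `journal_separation`) allow planting signal in
exactly one feature class for selection experiments.

What the generator does **not** emulate: real English word
frequencies, token dependence (draws are i.i.d., so bigrams and
trigrams carry no signal beyond their unigrams), topical correlation
between title and abstract, MeSH co-assignment structure, and temporal
drift. Passing the synthetic benchmarks therefore demonstrates that the
pipeline recovers a known generative signal and calibrates correctly —
not that any particular accuracy will be achieved on real curated
corpora, where performance depends on the actual separability of the
classes.

## Problem sizes and numerical choices

Benchmarks run at desk scale, chosen once: the calibration-recovery
benchmark uses 20 000 records (16 000 train / 4 000 held out), the
selection experiments 1 200 records per seed over ten seeds, and unit
fixtures hundreds of records. The reliability-R² study lowers the
token separation to 0.8 so mid-range probability bins are populated —
with well-separated classes nearly all scores land near 0 or 1 and a
reliability line fitted through near-empty bins is meaningless.

Vocabulary pruning uses `min_df = 2` (a token must appear in at least
two records), controlling feature-space size at desk scale without
changing the method. All randomness flows through explicit integer
seeds (fold plans, internal calibration splits, the SVM's coordinate
descent, the generator), and tagger archives contain no timestamps, so
every pipeline stage is bit-reproducible. Degenerate inputs fail
loudly: single-class labels, empty corpora, empty feature-class sets
and malformed XML raise errors rather than producing partial results;
unparseable pagination degrades to a page count of 0 with a warning.

## Known limitations

- The calibrator family is a standard monotone substitute with the
  same contract as specialized margin-mapping methods; no claim is
  made to reproduce any particular published calibration algorithm.
- Isotonic calibration can be piecewise-constant over wide margin
  ranges when the calibration split is small; the sigmoid option is
  smoother but parametric.
- The pagination parser handles numeric ranges, bare pages and
  electronic identifiers; exotic pagination ("iv-ix", "suppl 1")
  counts 0.
- Scores for citations whose every token is out-of-vocabulary collapse
  to the calibrated bias — correct behavior, but worth knowing when
  tagging text from a very different domain.
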