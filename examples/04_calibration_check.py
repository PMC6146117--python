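"""Check that predicted probabilities mean what they say.

A probability of 0.8 should be right 80% of the time.  This script
bins held-out predictions into 5%-wide score ranges and compares each
bin's mean predicted probability with (a) the observed fraction of
positive labels and (b) the known generative posterior — the latter
is only possible because the corpus is synthetic.
"""

import numpy as np

from humtag import (Corpus, FeatureClass, TaggerConfig,
                    calibration_adjusted_r2, calibration_curve,
                    mean_calibration_error, train_tagger)
from humtag.synthetic import generate, medline_like

gen = generate(medline_like(n_records=8000, seed=3, separation=0.8))
recs = gen.corpus.records
train_c, test_c = Corpus(recs[:6400]), Corpus(recs[6400:])

tagger = train_tagger(
    train_c,
    [FeatureClass.TITLE_UNIGRAM, FeatureClass.ABSTRACT_UNIGRAM,
     FeatureClass.JOURNAL_NAME],
    TaggerConfig(seed=3))

scores = tagger.tag_corpus(test_c)
labels = np.array([r.label for r in test_c], dtype=bool)

curve = calibration_curve(scores, labels, bin_width=0.05)
print("score range   n     mean score   observed fraction")
for b in curve.bins:
    if b.n >= 30:
        print(f"[{b.lo:.2f},{b.hi:.2f})  {b.n:>5}   {b.mean_score:.3f}        "
              f"{b.proportion:.3f}")

mace = mean_calibration_error(scores, gen.posterior[6400:])
r2 = calibration_adjusted_r2(curve, min_bin_n=30)
print(f"\nmean |predicted - true posterior|: {mace:.4f}  (good if < 0.05)")
print(f"reliability-curve adjusted R^2:    {r2:.4f}  (1.0 = perfectly linear)")
# Bins should hug the diagonal: predicted ~ observed in every
# well-populated score range.
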