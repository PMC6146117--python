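"""Audit extreme disagreements between the tagger and the index.

When the index says "human" but the tagger is near-certain it is not
(score < 0.01), or vice versa (score > 0.99), somebody is wrong.
These cases are sampled for blinded manual review; once a reviewer
fills in HUMAN / NOT_HUMAN / UNCERTAIN verdicts, agreement_stats
turns the counts into percent agreement with the model.

Here the review counts are a worked example: in the low-score stratum
97 of 100 reviews said not-human (agreeing with the model), in the
high-score stratum 50 of 100 said human.
"""

from humtag import AgreementTable, agreement_stats

# (humans, not_humans, uncertain) verdict counts per stratum
table = AgreementTable(
    low=(2, 97, 1),     # index positive, tagger score < 0.01
    high=(50, 41, 9),   # index negative, tagger score > 0.99
)

stats = agreement_stats(table)
print(f"low-score stratum agreement:  {stats.low_pct:.1f}%")
print(f"high-score stratum agreement: {stats.high_pct:.1f}%")
print(f"overall agreement:            {stats.overall_pct:.1f}%")
# A high low-stratum agreement means a near-zero score is a safe
# discard; a ~50% high-stratum agreement means a near-one score on an
# unindexed-negative record is genuinely ambiguous.
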