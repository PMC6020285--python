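"""Classify and rank-sum-prioritize concordant genes from fold changes.

Builds a handful of common genes with oriented fold changes from both
experiments (activation arm as treated/vehicle, inhibition arm as
vehicle/inhibitor), classifies them by sign concordance, and ranks the
positive class by the sum of its per-experiment fold-change ranks.
"""

from crossde.concord import (
    CONCORDANT_POSITIVE,
    ConcordantGene,
    rank_concordant,
)

# fold changes in the style of a pathway-activation screen: strong induction
# in vitro, attenuated induction in vivo (vehicle/inhibitor orientation)
genes = [
    ConcordantGene("Gli1", 25.62, 9e-6, 1.61, 0.10, CONCORDANT_POSITIVE),
    ConcordantGene("Hhip", 14.91, 1e-6, 1.56, 0.12, CONCORDANT_POSITIVE),
    ConcordantGene("Ptch2", 8.68, 9e-6, 1.55, 0.006, CONCORDANT_POSITIVE),
    ConcordantGene("Foxf2", 2.43, 4.1e-5, 1.83, 0.18, CONCORDANT_POSITIVE),
    ConcordantGene("Foxd1", 6.37, 5.6e-5, 1.44, 0.38, CONCORDANT_POSITIVE),
]

table = rank_concordant(genes, top_k=0)
print(table.frame.to_string(index=False))
# rank_vitro/rank_vivo are the within-class fold-change ranks (1 = largest
# induction); rank_sum adds them, so the top rows are genes strongly induced
# in BOTH experiments — joint-evidence prioritization that no single arm's
# p-value ordering provides. Ties in rank_sum break by smaller in vitro FDR.
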