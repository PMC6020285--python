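"""Hypergeometric over-representation of a custom gene category.

Tests whether a disease-associated gene list is over-represented among a
query set (e.g. the concordant pathway-regulated genes) relative to an
explicit background universe of measured genes.
"""

from crossde import GeneSetCategory, enrich

background = {f"g{i}" for i in range(2000)}          # all measured genes
query = {f"g{i}" for i in range(112)}                # e.g. concordant genes
category = GeneSetCategory(
    name="disease_associated",
    source="published_compilation",
    members=tuple(f"g{i}" for i in range(0, 700, 5)),  # 140 genes, 23 in query
)

(result,) = enrich(query, [category], background)
print(f"background N={result.N}, category K={result.K}, query n={result.n}")
print(f"overlap k={result.k}")
print(f"fold enrichment = {result.fold_enrichment:.3f}")
print(f"hypergeometric P(X >= k) = {result.p:.3e}")
# fold enrichment is observed/expected overlap: (k/n)/(K/N). Values > 1 with
# a small upper-tail p indicate the category is over-represented in the
# query beyond what drawing n genes at random from the background gives.
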