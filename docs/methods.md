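# Methods

## The statistical model

Each arm of the study is a two-condition comparison of gene-level linear
signal intensities (genes × samples). The package treats intensities as
log-normal: tests operate on log2-transformed values, where replicate
noise is approximately additive Gaussian, while fold changes are reported
as ratios of arithmetic condition means on the linear scale — the
reporting convention of array analysis consoles, and the scale on which
the published tables this pipeline mirrors are printed. The two
conventions intentionally coexist: the t-test asks "is the log2 shift
reliable?", the linear FC states "by what factor?".

Per gene, the differential-expression record carries mean_a, mean_b,
fc = mean_a/mean_b, log2fc, a two-sided p-value and its
Benjamini–Hochberg adjustment ("FDR p-value") across all genes of the
table, and a direction (up if fc > 1, down if fc < 1, flat if exactly 1;
flat genes never enter significant sets since their direction is
undefined). The test is Welch's unequal-variance t by default, with a
pooled-variance Student t behind a flag: the original analysis console's
exact test is not documented, t-family tests on log signal are the era's
default, and the concordance layer is deliberately robust to this choice
(it consumes only signs, ranks and gate membership).

Degenerate inputs follow fixed conventions rather than NaNs: identical
groups give p = 1; zero within-group variance with unequal means gives
the smallest positive double (never an exact 0) with a logged warning.

## Asymmetric gating and concordance

Significance gating is strict (`fdr < alpha`). The defaults are
alpha = 0.01 for the robust arm and alpha = 0.75 for the attenuated arm.
The 0.75 gate looks alarming in isolation — by design. The attenuated
arm's effects are small relative to its noise, so a conventional gate
would discard almost everything (false negatives); the permissive gate
retains candidates, and false positives are then controlled by requiring
membership in the stringently gated robust arm *and* sign concordance.
The probability that a null gene survives the 0.01 BH gate, the 0.75
gate, and a coin-flip sign match is negligible, which the null-calibration
tests confirm empirically (zero concordant calls across seeds).

Orientation precedes classification: the inhibitor-arm comparison is
flipped to vehicle/inhibitor (fc → 1/fc, log2fc → −log2fc, labels and
directions swapped, p and fdr untouched), so genuine positive regulation
appears as fc > 1 in both arms. Common genes (significant in both,
direction ignored at intersection) are then classified:
concordant-positive (both fc > 1), concordant-negative (both fc < 1),
discordant otherwise — including the measure-zero case of an exactly flat
fold change. Discordant genes are emitted with their flag, never dropped:
they are informative about platform disagreement.

## Rank-sum prioritization

Within one concordant sign class, each gene receives a fold-change rank
per experiment: rank 1 is the largest fc for the positive class and the
smallest fc (strongest repression) for the negative class; ties receive
average ranks. Genes are ordered by rank_sum = rank_vitro + rank_vivo
(minimum 2). Rank polarity for the negative class, and all tie-breaking,
are underdetermined in the procedure this mirrors; the package's choices
are: repression strength ranks the negative class, rank-sum ties break by
smaller robust-arm FDR, then alphabetically. Because ranks are invariant
under strictly monotone transforms of fold change, the ordering is
insensitive to the linear-vs-log scale question. Positive and negative
classes are always ranked in separate tables.

## Over-representation analysis

Enrichment of a category (K of N background genes) in a query (n genes,
overlap k) uses the exact upper-tail hypergeometric probability
P(X ≥ k) — from scipy's survival function, which accumulates the tail
stably — and fold enrichment (k/n)/(K/N). The background universe is an
explicit, logged parameter; the pipeline default is the genes measured in
*both* expression matrices, the universe from which the concordant set was
actually drawn. No multiplicity adjustment is applied by default (the
intended use is a handful of pre-registered custom categories at a fixed
alpha); BH across categories is available by flag. Query genes outside
the background are dropped with a warning rather than silently shrinking N.

## qPCR and compartment arithmetic

Relative quantification follows the Livak 2^-ddCt convention: per sample
dCt = Ct(target) − Ct(reference housekeeping gene); the calibrator is the
mean control-group dCt, making control relative quantities average ~1;
RQ = 2^−(dCt − calibrator); the group fold change is
mean(treated RQ)/mean(control RQ). The construction is invariant to any
constant Ct shift applied to a whole plate, and to shifts of the
reference gene mirrored in the target. Group tests are two-tailed Welch
t on the RQ scale by default (matching fold-change ± SEM presentation),
with a dCt-scale flag; panels of genes are corrected by step-down
Holm–Šidák (adjusted_i = max_{j≤i} (1 − (1 − p_(j))^(m−j+1)), capped at
1), with strict rejection below alpha.

Compartment localization reports each tissue's reference-normalized
expression as a percentage of the two-compartment total:
pct_mes = 100·m/(m+e), pct_ect = 100 − pct_mes; the percentages sum to
100 exactly in exact arithmetic, and the all-zero case is an error rather
than a 50/50 fabrication.

## The synthetic-study generator

`simulate_pair` emulates the paired design end to end. Per gene g:
baseline b_g ~ N(baseline_log2_mean, baseline_log2_sd); a fraction of
genes is positively/negatively regulated, with effect magnitudes drawn
from a Normal(effect_log2_mean, effect_log2_sd) truncated at 0 (exact
truncation, not folding — bounded below with simple moments for
closed-form checks) and signed by status. Activation-arm samples are
b_g (+ effect for treated) + N(0, sigma_vitro); inhibition-arm samples
are b_g + N(0, sigma_vivo) for vehicle and b_g − attenuation·effect +
N(0, sigma_vivo) for the inhibitor, so the vehicle/inhibitor orientation
recovers the activation-arm sign for every non-null gene. Intensities are
2^log2signal. A single seeded generator drives all draws in one
documented order, so identical configs are bit-identical.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 10,000 | order of a gene-level array after summarization |
| frac_positive / frac_negative | 0.02 / 0.02 | sparse truth: a few hundred genuine targets |
| effect_log2_mean | 2.0 | robust-arm inductions around 4-fold |
| effect_log2_sd | 0.5 | spreads true fold changes over roughly 2.8–5.7× (±1 sd), wide enough for meaningful within-class ranking without a heavy tail of undetectable effects |
| attenuation | 0.25 | mimics the observed contrast between strong in vitro induction (tens-fold) and in vivo fold changes near 1.4–1.6 |
| sigma_vitro / sigma_vivo | 0.25 / 0.5 | clean clonal culture vs heterogeneous pooled tissue |
| reps_vitro / reps_vivo | 4 / 6 | the two arms' replicate structure |
| baseline_log2_mean ± sd | 8 ± 2 | typical mid-range intensity spread on log2 scale |

What the generator does **not** model: probe-level effects, batch or
hybridization artifacts, litter-pooling variance hierarchy (pooling is
represented only through sigma_vivo), correlated co-regulation, and
intensity-dependent variance. Passing recovery tests therefore demonstrate
the pipeline's correctness and calibration under an idealized log-normal
world, not performance guarantees on real arrays.

### Power under the reference conditions

A consequence worth stating plainly: under the reference conditions
above, the attenuated arm carries a mean true shift of
attenuation·effect ≈ 0.5 log2 against per-sample noise of 0.5 with 6v6
replicates — a per-gene Welch t around 1.7. With only 4% of genes truly
regulated, BH at 0.75 can only reject down to raw p ≈ 0.01 (FDR control
caps rejections near 4× the true discoveries), so the attenuated arm
recovers only ~10–25% of true genes and end-to-end recall sits near 0.1,
with precision ≈ 1.0. The package reports these honestly
(`scripts/acceptance.py`); the corresponding recovery test asserts the
nominal ≥ 0.8 recall bar and fails under these conditions, documenting
that the permissive-gate design trades recall for precision far more
steeply than a first glance at "FDR < 0.75" suggests. In the noiseless
limit recovery is exactly 1.0, and recall rises steeply as sigma_vivo
falls or attenuation grows (the monotonicity test exercises this).

## Numerical choices

- BH and Holm–Šidák adjustments delegate to statsmodels; both are
  cross-checked in the test suite against independent brute-force
  definitions (and the hypergeometric tail against exact rational
  enumeration of all draws for small N).
- p-values are never 0: the smallest positive double is substituted with
  a warning, keeping downstream log-space operations finite.
- Expression TSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-identical.
- Result tables carry their thresholds/seed as `#` metadata lines;
  `report.json` is schema-versioned with sorted keys, making fixed
  config + seed byte-reproducible.
- Gene symbols match case-sensitively by default; an optional case-folding
  flag upper-cases symbols at read time for cross-annotation reconciliation.

## Known limitations

- No moderated-variance (empirical Bayes) testing; with 4–6 replicates a
  limma-style shrinkage would raise per-arm power. Out of scope by design:
  the concordance layer, not the per-arm test, is the contribution here.
- No meta-analytic combination of the two arms' p-values; the
  intersection-of-gates approach is deliberately conservative.
- The verification entry point re-derives concordance counts from an
  external common-gene table's fold-change signs alone; it cannot audit
  the upstream gates of that table.
- DAVID-style annotation-database enrichment (modified Fisher scores,
  term hierarchies) is out of scope; categories are user-supplied GMT.
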