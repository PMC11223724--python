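# Methods

## The cross-table counting rule

The unit of counting is the case, not the mention.  A keyword takes one of
three states per case: positive, negative, or null (never mentioned).  For a
(diagnosis *d*, keyword *k*) pair,

- TP = cases with *d* whose state for *k* is positive,
- TN = cases without *d* whose state is negative,
- FP = (total positive annotations of *k*) − TP,
- FN = (total negative annotations of *k*) − TN.

Null states contribute to no cell, so the 2×2 table generally covers only a
subset of cases.  The subtraction form is equivalent to counting FP as
positives among cases without the diagnosis and FN as negatives among cases
with it; the package asserts the resulting conservation identities
(TP+FP = positive total, FN+TN = negative total) in its tests.  Whether the
original tallies behind this design counted repeated mentions of a keyword
within one record multiply is not decidable from the published summaries;
this implementation collapses repeats to one annotation per (case, keyword)
— the cross-table arithmetic requires one contribution per patient — and
resolves positive/negative conflicts in favour of positive (an asserted
finding anywhere in a record outweighs a negation).  Both events are logged
and counted on the `Corpus` object.

A metric is *calculable* when its denominator cells sum to ≥ 1; the
likelihood ratios additionally need all four cells ≥ 1.  Non-calculable
metrics are flagged, never raised, because the emptiness of the cross table
is itself the quantity of interest.

## Intervals and tests

- Proportion CIs: Wilson score by default, switching to Clopper–Pearson
  when any cell of the 2×2 is below 5 (`ci_method="auto"`; both methods are
  also selectable directly).  The threshold follows the usual small-sample
  practice; published interval values for n = 2 and n = 4 cells match the
  Wilson score interval, which is why Wilson remains the base method.
- Likelihood-ratio CIs: log-transform method,
  SE(ln LR⁺) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) and the mirrored
  expression for LR⁻.  The reference tables this was checked against agree
  closely but not exactly, and the original method is unstated, so LR
  interval endpoints are validated against the formula, not against
  published values.
- Chi-squared screening: uncorrected Pearson on the 2×2 (df = 1), Yates
  correction available via flag.  A table with a zero margin carries no
  testable association and is reported as statistic 0, p = 1; an all-zero
  table is an error.  Screening uses raw p < α (matching the original
  analysis); Bonferroni and Benjamini–Hochberg adjustments are available
  but off by default.
- Two-proportion comparisons: pooled z-test,
  z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), two-sided normal p; undefined when
  the pooled proportion is 0 or 1 (reported as NaN in the stratified
  report).

## Long-tail diagnostics

Keyword frequencies are tabulated per stratum: section strata (Hx/Px) take
a keyword's full annotation count; polarity strata count only annotations
of that polarity over keywords having at least one.  Sorting is by count
descending with lexicographic tie-break, making top-k% segments
deterministic; the top-k% segment holds ⌈k/100·m⌉ keywords.  The Gini
coefficient uses the population estimator (no m/(m−1) correction): the
trapezoid-integrated empirical Lorenz curve under G = 2(½ − ∫L), which on
discrete data coincides with the pairwise mean-absolute-difference form
G = Σᵢⱼ|xᵢ−xⱼ|/(2m²x̄); the two are cross-checked to 1e-9.

## Accumulation models

Cumulative annotation, unique-keyword and diagnosis counts are computed by
walking cases in input order; a permutation-averaged mode (rarefaction
style, seeded) is provided because a synthetic corpus has no natural visit
order and the early part of the curve is order-sensitive (endpoints are
not).  The default full-analysis configuration uses input order with the
permuted mode opt-in.

The four families are fit as follows: linear and logarithmic by OLS
(statsmodels, giving parameter standard errors); the power family by OLS of
ln y on ln x, with R² reported on that log-log fitting scale; the
power+constant family y = axᵇ + c by damped nonlinear least squares
(scipy's Levenberg–Marquardt via `curve_fit`, ftol = xtol = 1e-8, at most
10,000 evaluations) initialised from the log-log power fit with c₀ = 0, its
standard errors from the Jacobian-based covariance and
R² = 1 − RSS/TSS(corrected).  Model selection is by maximal R² with exact
ties broken toward fewer parameters.  Extrapolation evaluates the selected
model's prediction function (the power model back-transforms from logs) and
rounds halves away from zero to integers, keeping the raw values alongside;
predictions outside the fitted range are reported without clamping, so a
linear model can go negative at x = 0.

All printed rates, ratios and percentages round halves away from zero (2
decimals for per-case rates and percentages, 1 for ratios), matching the
conventions of the tables this analysis style is reported in.

## The synthetic generator

No raw records are distributable, so every downstream stage is exercised on
synthetic corpora whose defaults encode the study conditions: 270 cases; 26
ICHD-II codes with the published skewed case mix (e.g. code 14 at 73/270,
code 1 at 36/270); inventories of 521 Hx and 102 Px keywords; mean
annotations per case 3,789/270 (Hx) and 3,115/270 (Px); positive-annotation
rates 2,566/3,789 (Hx) and 174/3,115 (Px).  Per case, the annotation count
per section is Poisson truncated to the inventory size (the simplest count
law matching a mean; swappable), keywords are drawn without replacement
under a rank-popularity law P(rank r) ∝ r^(−s) — implemented exactly via
the Gumbel-top-k equivalence — and polarity is i.i.d. per section.  The
exponent s = 1.15 was calibrated once so the realized total-stratum Gini of
the default corpus is ≈ 0.72 (matching the observed ≈ 0.7 inequality);
s ≥ 1 keeps the realized Gini above 0.5 across seeds.  All draws come from
one `numpy` Generator seeded with the config seed, so identical configs
yield byte-identical corpora.

Planted associations give a keyword a fully determined emission: cases with
the diagnosis receive a positive annotation with probability equal to the
planted sensitivity and a negative one otherwise; other cases receive a
negative annotation with probability equal to the planted specificity and a
positive one otherwise.  Every case is thus annotated for that keyword and
the cell's estimated sensitivity/specificity are binomial estimates of the
planted values — this is what makes end-to-end parameter-recovery tests
possible.  When several associations name one keyword, the last appended
wins.

What the generator does *not* emulate: free text and extraction error,
annotator disagreement, keyword co-occurrence structure, per-diagnosis
keyword profiles (outside planted pairs), or temporal/seasonal case mix.
Passing tests therefore demonstrate that the estimators and accounting are
correct under the stated statistical structure, not that any particular
clinical corpus has that structure.  Realized corpora also differ from
their nominal parameters in expected ways: at 270 cases, rare diagnoses
(probability 1/270) are sometimes absent and tail keywords undrawn, so a
default corpus shows ~23 diagnoses and ~550 observed keywords.

## Problem sizes and numerical choices

Tests run the default 270-case corpus for end-to-end checks; parameter
recovery uses 50 replicates of 5,000 cases with a reduced inventory (50 Hx
/ 20 Px keywords), which keeps the binomial denominators large (~1,500 and
~3,500) while exercising the full generate→count→estimate path; interval
coverage uses 2,000 binomial draws at p = 0.3, n = 50.  These sizes give
the coverage assertions comfortable Monte-Carlo margins under the fixed
seeds used.  Degenerate inputs (empty corpora, all-zero distributions,
constant designs, zero-margin tables) either raise typed errors or are
flagged and reported, as documented per function.

## Known limitations

- Corpus-level: the TSV form cannot represent a case with zero annotations
  (JSON can); duplicate-mention information is discarded at ingestion.
- The diagnosis axis is single-label; comorbid codings would need a
  multi-label extension of the counting rule.
- The power-family R² is a log-log quantity and not directly comparable to
  the other families' original-scale R²; model selection nevertheless
  follows the conventional practice of comparing the reported R² values.
- Extrapolations are point projections of the fitted mean curve; no
  uncertainty bands are produced.
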