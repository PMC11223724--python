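# keywordlr

Can a clinical decision support system based on Bayes' theorem be fed by
exhaustively harvesting keywords from medical records?  `keywordlr` is a
toolkit for answering that question quantitatively.  It targets corpora in
which every case (patient record) carries a diagnosis code (e.g. ICHD-II
headache codes) and a set of *annotated keywords*: clinical findings tagged
as asserted (`pos`) or negated (`neg`), each belonging to either the history
(`Hx`) or the physical-examination/tests (`Px`) section.  From such a corpus
the package derives:

- **Diagnosis × keyword cross tables.**  For each pair, TP = cases with the
  diagnosis and a positive annotation, TN = cases without the diagnosis and a
  negative annotation; FP and FN follow by subtracting TP and TN from the
  keyword's positive and negative totals.  Cases where the keyword never
  appears (null) contribute to no cell.  Each cell yields the six
  operational characteristics — sensitivity, specificity, PPV, NPV, and the
  likelihood ratios LR⁺ = sens/(1−spec), LR⁻ = (1−sens)/spec — with Wilson
  or Clopper–Pearson confidence intervals, chi-squared screening, and an
  accounting of how many cells are *calculable* at all (LRs need all four
  cells ≥ 1).
- **Long-tail diagnostics.**  Keyword-frequency histograms per stratum,
  proportions of keywords with frequency ≥ 4 (the floor for a complete cell)
  or exactly 1, top-1/10/20 % concentration shares, Lorenz curves and the
  Gini coefficient G = 2(½ − ∫₀¹L(F)dF), and pooled two-proportion z-tests
  between strata.
- **Vocabulary accumulation models.**  Cumulative annotation, unique-keyword
  and diagnosis counts as cases accrue, fitted with four families —
  y = ax+b, y = a ln x + b, ln y = a ln x + b, and the nonlinear
  y = axᵇ + c — selected by R² and extrapolated to theoretical case counts
  (10¹–10⁵) to project how slowly a cross table would fill.
- **A synthetic corpus generator** reproducing the statistical structure
  such corpora exhibit (≈270 cases, 26-code skewed diagnosis mix, 521 Hx +
  102 Px keywords, Zipf-like keyword popularity with Gini ≈ 0.7,
  section-specific polarity rates), with the option of *planting*
  diagnosis–keyword associations of known sensitivity/specificity so the
  whole pipeline can be validated by parameter recovery.

## Worked example

```python
from keywordlr import (default_config, generate_corpus, build_cross_table,
                       calculability_summary, significant_combinations,
                       longtail_report, accumulation_curves,
                       GrowthCurveModel, select_best_model, extrapolate)

corpus = generate_corpus(default_config(seed=1))
print(corpus)
# <Corpus: 270 cases, 23 diagnoses, 546 keywords, 6903 annotations>

table = build_cross_table(corpus)
print(calculability_summary(table).table().loc[["lr"]])
#               Hx          Px       total
# lr    287 (2.81)   84 (3.58)  371 (2.95)

print(len(significant_combinations(table, alpha=0.05)))
# 14

print(longtail_report(corpus).frame[["n_uk", "pct_eq1", "gini"]].round(3))
#         n_uk  pct_eq1   gini
# Hx     444.0     26.1  0.710
# Px     102.0      0.0  0.579
# pos    453.0     37.7  0.681
# neg    390.0     35.9  0.734
# total  546.0     21.2  0.722

curves = accumulation_curves(corpus)
fits = GrowthCurveModel(curves.x, curves.unique_keywords).fit_all()
best = select_best_model(fits.values())
print(best.model, round(best.rsquared, 4))
# power_plus_constant 0.9978
print(extrapolate(best, [10, 100, 1000, 10000, 100000]).rounded)
# [ 140.  398.  822. 1520. 2669.]
```

Reading: of the 12,558 diagnosis–keyword cells only 371 (2.95 %) admit a
likelihood ratio, and just 14 pairs survive chi-squared screening at
α = 0.05 — the cross table stays almost empty even though every record was
"fully" annotated.  The keyword frequencies are strongly unequal
(Gini 0.72): a few findings dominate while a fifth of keywords occur once.
New vocabulary decelerates as a power law with offset (R² = 0.998), so even
10⁵ cases would surface only ≈2,700 unique keywords — the sublanguage
closes long before the cross table fills.

The same pipeline runs from the shell:

```sh
keywordlr simulate --seed 1 --out corpus.tsv
keywordlr crosstab --corpus corpus.tsv --out cells.tsv
keywordlr longtail --corpus corpus.tsv --out longtail.json --plot figures/
keywordlr accumulate --corpus corpus.tsv --out fits.json
keywordlr report --corpus corpus.tsv --seed 1 --out report/
```

Real corpora are ingested from a 5-column TSV
(`case_id diagnosis keyword section polarity`) or an equivalent JSON
dialect; see `keywordlr.read_corpus`.

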