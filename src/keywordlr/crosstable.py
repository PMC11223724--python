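"""Diagnosis x keyword cross tables and operational characteristics.

For every (diagnosis, keyword) pair a 2x2 contingency table is assembled
from the corpus with the counting rule:

* TP — cases with the diagnosis carrying a positive annotation of the
  keyword;
* TN — cases *without* the diagnosis carrying a negative annotation;
* FP — the keyword's total positive annotations minus TP;
* FN — the keyword's total negative annotations minus TN.

Cases for which the keyword is null (never mentioned) contribute to no
cell.  Under this rule FP is exactly the positives among cases without the
diagnosis and FN the negatives among cases with it, so the usual
conservation identities hold: TP+FP is the keyword's positive total and
FN+TN its negative total.

From each cell the six operational characteristics are derived —
sensitivity, specificity, PPV, NPV and the positive/negative likelihood
ratios (LR+ = sens/(1-spec), LR- = (1-sens)/spec) — each flagged as
calculable only when its denominator cells allow it; the likelihood ratios
require all four cells >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .corpus import Corpus
from ._util import percentage

__all__ = [
    "ContingencyCounts",
    "OpChar",
    "CrossTable",
    "CalculabilityReport",
    "SignificantCombination",
    "contingency",
    "build_cross_table",
    "proportion_ci",
    "operational_characteristics",
    "chi_squared_2x2",
    "calculability_summary",
    "significant_combinations",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv", "plr", "nlr")


class LookupError_(KeyError):
    """Unknown diagnosis or keyword."""


class DegenerateTableError(ValueError):
    """A statistic is undefined on this table (e.g. all cells zero)."""


@dataclass(frozen=True)
class ContingencyCounts:
    """TP/FP/FN/TN cell counts for one (diagnosis, keyword) pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass
class OpChar:
    """Operational characteristics with confidence intervals.

    A metric is ``None`` exactly when its ``calculable`` flag is False.
    Proportion CIs use the Wilson score or Clopper-Pearson interval;
    likelihood-ratio CIs use the log-transform method with
    ``SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn))`` (and the
    mirrored expression for LR-).
    """

    counts: ContingencyCounts
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    plr: float | None = None
    nlr: float | None = None
    ci: dict = field(default_factory=dict)
    calculable: dict = field(default_factory=dict)
    chi2_stat: float | None = None
    p_value: float | None = None

    def as_dict(self) -> dict:
        out = {"tp": self.counts.tp, "fp": self.counts.fp,
               "fn": self.counts.fn, "tn": self.counts.tn}
        for m in METRICS:
            out[m] = getattr(self, m)
            lo, hi = self.ci.get(m, (None, None))
            out[f"{m}_lo"], out[f"{m}_hi"] = lo, hi
            out[f"{m}_calculable"] = self.calculable.get(m, False)
        out["chi2"] = self.chi2_stat
        out["p"] = self.p_value
        return out


class CrossTable:
    """All (diagnosis, keyword) contingency cells of a corpus.

    Cell counts are stored as four integer matrices indexed by diagnosis
    (rows) and keyword (columns), both sorted lexicographically.
    """

    def __init__(
        self,
        tp: pd.DataFrame,
        fp: pd.DataFrame,
        fn: pd.DataFrame,
        tn: pd.DataFrame,
        sections: dict[str, str],
    ) -> None:
        self.tp, self.fp, self.fn, self.tn = tp, fp, fn, tn
        self.sections = sections

    @property
    def diagnoses(self) -> list[str]:
        return list(self.tp.index)

    @property
    def keywords(self) -> list[str]:
        return list(self.tp.columns)

    @property
    def n_cells(self) -> int:
        return self.tp.size

    def __getitem__(self, key: tuple[str, str]) -> ContingencyCounts:
        d, k = key
        if d not in self.tp.index:
            raise LookupError_(f"unknown diagnosis {d!r}")
        if k not in self.tp.columns:
            raise LookupError_(f"unknown keyword {k!r}")
        return ContingencyCounts(
            int(self.tp.at[d, k]), int(self.fp.at[d, k]),
            int(self.fn.at[d, k]), int(self.tn.at[d, k]),
        )

    def cells(self) -> Iterator[tuple[str, str, ContingencyCounts]]:
        for d in self.diagnoses:
            for k in self.keywords:
                yield d, k, self[d, k]

    def lr_calculable_mask(self) -> pd.DataFrame:
        """Boolean matrix: all four cells >= 1 (LRs calculable)."""
        return (self.tp >= 1) & (self.fp >= 1) & (self.fn >= 1) & (self.tn >= 1)

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per cell with the four counts."""
        rows = []
        for d, k, c in self.cells():
            rows.append((d, k, self.sections.get(k, ""), c.tp, c.fp, c.fn, c.tn))
        return pd.DataFrame(
            rows, columns=["diagnosis", "keyword", "section", "tp", "fp", "fn", "tn"]
        )


def _pivot_counts(corpus: Corpus, polarity: str) -> pd.DataFrame:
    long = corpus.to_frame()
    sub = long[long["polarity"] == polarity]
    mat = pd.crosstab(sub["diagnosis"], sub["keyword"])
    return mat.reindex(
        index=corpus.diagnoses, columns=corpus.keywords, fill_value=0
    ).astype(int)


def build_cross_table(corpus: Corpus) -> CrossTable:
    """Assemble every contingency cell of the corpus in one pass."""
    if corpus.n_keywords == 0 or not corpus.diagnoses:
        raise ValueError("corpus has an empty inventory or diagnosis set")
    pos = _pivot_counts(corpus, "pos")
    neg = _pivot_counts(corpus, "neg")
    tot_pos = pos.sum(axis=0)
    tot_neg = neg.sum(axis=0)
    tp = pos
    fn = neg
    fp = (tot_pos - pos).astype(int)
    tn = (tot_neg - neg).astype(int)
    return CrossTable(tp, fp, fn, tn, corpus.section_of())


def contingency(corpus: Corpus, diagnosis: str, keyword: str) -> ContingencyCounts:
    """Contingency cell for one (diagnosis, keyword) pair."""
    if diagnosis not in set(corpus.cases["diagnosis"]):
        raise LookupError_(f"unknown diagnosis {diagnosis!r}")
    if keyword not in set(corpus.inventory["keyword"]):
        raise LookupError_(f"unknown keyword {keyword!r}")
    long = corpus.to_frame()
    sub = long[long["keyword"] == keyword]
    has_dx = sub["diagnosis"] == diagnosis
    is_pos = sub["polarity"] == "pos"
    tp = int((has_dx & is_pos).sum())
    fn = int((has_dx & ~is_pos).sum())
    fp = int(is_pos.sum()) - tp
    tn = int((~is_pos).sum()) - fn
    return ContingencyCounts(tp, fp, fn, tn)


# ---------------------------------------------------------------------- #
# intervals and tests


def proportion_ci(
    k: int, n: int, method: str = "wilson", alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided (1-alpha) binomial interval for k successes out of n.

    ``method`` is ``"wilson"`` (score interval) or ``"clopper_pearson"``
    (exact).  The exact interval is preferred for sparse cells.
    """
    if n < 1:
        raise DegenerateTableError("interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return float(lo), float(hi)


def chi_squared_2x2(
    counts: ContingencyCounts, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test (df=1) on the 2x2 cell.

    ``correction`` applies Yates' continuity correction.  A table with a
    zero margin carries no testable association: statistic 0, p 1.  An
    all-zero table is an error.
    """
    tp, fp, fn, tn = counts.as_tuple()
    if counts.total == 0:
        raise DegenerateTableError("chi-squared undefined on an all-zero table")
    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def _resolve_ci_method(counts: ContingencyCounts, ci_method: str) -> str:
    # sparse cells (< 5) get the exact interval under the auto policy
    if ci_method == "auto":
        return "clopper_pearson" if min(counts.as_tuple()) < 5 else "wilson"
    return ci_method


def operational_characteristics(
    counts: ContingencyCounts, ci_method: str = "auto", alpha: float = 0.05
) -> OpChar:
    """Six operational characteristics of one contingency cell.

    Each proportion is calculable iff its denominator is >= 1; the
    likelihood ratios require every cell >= 1.  Non-calculable metrics are
    flagged, never raised.
    """
    tp, fp, fn, tn = counts.as_tuple()
    method = _resolve_ci_method(counts, ci_method)
    oc = OpChar(counts=counts)
    z = stats.norm.ppf(1 - alpha / 2)

    for name, k, n in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, fp + tn),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        ok = n >= 1
        oc.calculable[name] = ok
        if ok:
            setattr(oc, name, k / n)
            oc.ci[name] = proportion_ci(k, n, method=method, alpha=alpha)

    lr_ok = min(tp, fp, fn, tn) >= 1
    oc.calculable["plr"] = oc.calculable["nlr"] = lr_ok
    if lr_ok:
        sens = tp / (tp + fn)
        spec = tn / (fp + tn)
        oc.plr = sens / (1 - spec)
        oc.nlr = (1 - sens) / spec
        se_plr = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        se_nlr = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        oc.ci["plr"] = (
            float(oc.plr * np.exp(-z * se_plr)),
            float(oc.plr * np.exp(z * se_plr)),
        )
        oc.ci["nlr"] = (
            float(oc.nlr * np.exp(-z * se_nlr)),
            float(oc.nlr * np.exp(z * se_nlr)),
        )

    if counts.total > 0:
        oc.chi2_stat, oc.p_value = chi_squared_2x2(counts)
    return oc


# ---------------------------------------------------------------------- #
# table-level accounting


@dataclass
class CalculabilityReport:
    """Counts and percentages of calculable cells per metric and stratum.

    ``counts``/``percents`` are DataFrames indexed by metric (sensitivity,
    specificity, ppv, npv, lr) with columns Hx, Px, total; ``totals`` are
    the stratum cell totals (|diagnoses| x stratum keyword count).
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    totals: dict[str, int]

    def table(self) -> pd.DataFrame:
        out = self.counts.astype(str)
        for col in out.columns:
            out[col] = [
                f"{int(c)} ({p})"
                for c, p in zip(self.counts[col], self.percents[col])
            ]
        return out


def calculability_summary(
    table: CrossTable, section_of: dict[str, str] | None = None
) -> CalculabilityReport:
    """How many cells allow each operational characteristic, by section."""
    if section_of is None:
        section_of = table.sections
    masks = {
        "sensitivity": (table.tp + table.fn) >= 1,
        "specificity": (table.fp + table.tn) >= 1,
        "ppv": (table.tp + table.fp) >= 1,
        "npv": (table.tn + table.fn) >= 1,
        "lr": table.lr_calculable_mask(),
    }
    kw = pd.Index(table.keywords)
    strata = {
        "Hx": kw[[section_of.get(k) == "Hx" for k in kw]],
        "Px": kw[[section_of.get(k) == "Px" for k in kw]],
        "total": kw,
    }
    n_dx = len(table.diagnoses)
    counts = pd.DataFrame(index=list(masks), columns=list(strata), dtype=int)
    pct = pd.DataFrame(index=list(masks), columns=list(strata), dtype=float)
    totals = {}
    for sname, cols in strata.items():
        total = n_dx * len(cols)
        totals[sname] = total
        for metric, mask in masks.items():
            c = int(mask[cols].to_numpy().sum()) if len(cols) else 0
            counts.loc[metric, sname] = c
            pct.loc[metric, sname] = percentage(c, total) if total else float("nan")
    return CalculabilityReport(counts.astype(int), pct, totals)


@dataclass
class SignificantCombination:
    diagnosis: str
    keyword: str
    section: str
    opchar: OpChar


def significant_combinations(
    table: CrossTable,
    alpha: float = 0.05,
    ci_method: str = "auto",
    correction: bool = False,
    multiplicity: str | None = None,
) -> list[SignificantCombination]:
    """LR-calculable cells whose chi-squared test is significant.

    ``multiplicity`` may be ``"bonferroni"`` or ``"fdr_bh"`` to adjust the
    p-values over the LR-calculable cells (off by default: the screening is
    at raw p < alpha).  Rows are sorted by section, keyword, diagnosis.
    """
    mask = table.lr_calculable_mask()
    pairs = [(d, k) for d in table.diagnoses for k in table.keywords if mask.at[d, k]]
    if not pairs:
        return []
    pvals = []
    stats_ = []
    for d, k in pairs:
        s, p = chi_squared_2x2(table[d, k], correction=correction)
        stats_.append(s)
        pvals.append(p)
    pvals = np.asarray(pvals)
    if multiplicity is not None:
        from statsmodels.stats.multitest import multipletests

        reject, pvals, _, _ = multipletests(pvals, alpha=alpha, method=multiplicity)
    else:
        reject = pvals < alpha

    out = []
    for (d, k), s, p, r in zip(pairs, stats_, pvals, reject):
        if not r:
            continue
        oc = operational_characteristics(table[d, k], ci_method=ci_method, alpha=alpha)
        oc.chi2_stat, oc.p_value = s, float(p)
        out.append(SignificantCombination(d, k, table.sections.get(k, ""), oc))
    out.sort(key=lambda c: (c.section, c.keyword, c.diagnosis))
    return out
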