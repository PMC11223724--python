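"""Long-tail diagnostics of keyword-frequency distributions.

The annotation frequency of clinical keywords is strongly skewed: a few
findings (nausea, vomiting, basic neurological signs) are mentioned in a
large share of records while many findings appear once.  This module
quantifies that skew with threshold proportions (how many keywords reach
the frequency >= 4 needed to populate a contingency cell, how many are
singletons), top-k% concentration shares, the empirical Lorenz curve and
Gini coefficient, and pooled two-proportion z-tests comparing strata
(history vs examination, positive vs negative).

The Gini coefficient is computed two ways which agree exactly on discrete
data: ``G = 2 (1/2 - ∫ L(F) dF)`` with the piecewise-linear empirical
Lorenz curve integrated by trapezoids, and the pairwise mean absolute
difference ``G = Σ_ij |x_i - x_j| / (2 m^2 x̄)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .corpus import Corpus
from ._util import percentage

__all__ = [
    "FrequencyDistribution",
    "LorenzCurve",
    "GiniResult",
    "ZTestResult",
    "ThresholdCounts",
    "LongtailReport",
    "frequency_distribution",
    "threshold_counts",
    "top_share",
    "top_segment",
    "lorenz_curve",
    "gini",
    "two_proportion_z",
    "longtail_report",
]

STRATA = ("Hx", "Px", "pos", "neg", "total")


class DegenerateDistributionError(ValueError):
    """The requested statistic is undefined on this distribution."""


class UndefinedStatisticError(ValueError):
    """A test statistic has no defined value for these inputs."""


@dataclass
class FrequencyDistribution:
    """Per-keyword annotation counts within one stratum, sorted descending.

    Ties in count are broken lexicographically by keyword so the ranking is
    deterministic.
    """

    stratum: str
    keywords: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.keywords) != len(self.counts):
            raise ValueError("keywords and counts length mismatch")
        order = np.lexsort((np.asarray(self.keywords, dtype=object), -self.counts))
        self.keywords = [self.keywords[i] for i in order]
        self.counts = self.counts[order]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_keywords(self) -> int:
        return len(self.counts)


def frequency_distribution(corpus: Corpus, stratum: str = "total") -> FrequencyDistribution:
    """Annotation counts per keyword in a stratum.

    Section strata (``Hx``/``Px``) take the keywords of that section with
    all their annotations; polarity strata (``pos``/``neg``) take keywords
    having at least one annotation of that polarity, counting only those
    annotations; ``total`` covers everything.
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    ann = corpus.annotations
    if stratum in ("Hx", "Px"):
        ann = ann[ann["section"] == stratum]
    elif stratum in ("pos", "neg"):
        ann = ann[ann["polarity"] == stratum]
    counts = ann.groupby("keyword").size()
    return FrequencyDistribution(
        stratum, counts.index.tolist(), counts.to_numpy(dtype=int)
    )


@dataclass
class ThresholdCounts:
    """How much of the inventory clears the cross-table frequency floor.

    A keyword needs frequency >= 4 before all four contingency cells can be
    populated; singletons (frequency 1) sit in the far tail.  Percentages
    are of the stratum's keyword inventory.
    """

    n_ge4: int
    n_eq1: int
    n_total: int
    pct_ge4: float
    pct_eq1: float


def threshold_counts(dist: FrequencyDistribution) -> ThresholdCounts:
    n_ge4 = int((dist.counts >= 4).sum())
    n_eq1 = int((dist.counts == 1).sum())
    m = dist.n_keywords
    return ThresholdCounts(
        n_ge4, n_eq1, m, percentage(n_ge4, m, 1), percentage(n_eq1, m, 1)
    )


def top_segment(dist: FrequencyDistribution, pct: float) -> tuple[int, int]:
    """(number of keywords, summed count) of the top ``pct``% of keywords.

    The segment holds the ``ceil(pct/100 * m)`` most frequent keywords;
    ties at the cutoff follow the deterministic descending sort.
    """
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    if dist.n_keywords == 0:
        raise DegenerateDistributionError("empty distribution has no top share")
    k = ceil(pct / 100 * dist.n_keywords)
    return k, int(dist.counts[:k].sum())


def top_share(dist: FrequencyDistribution, pct: float) -> float:
    """Fraction of all annotations held by the top ``pct``% of keywords."""
    _, s = top_segment(dist, pct)
    if dist.total == 0:
        raise DegenerateDistributionError("zero-total distribution has no share")
    return s / dist.total


@dataclass
class LorenzCurve:
    """Empirical Lorenz curve on m+1 grid points.

    ``F`` is the cumulative fraction of keywords (poorest first), ``L`` the
    cumulative share of annotations; the curve is piecewise linear between
    grid points, starts at (0, 0), ends at (1, 1) and lies on or under the
    diagonal.
    """

    F: np.ndarray
    L: np.ndarray


def _as_counts(dist) -> np.ndarray:
    if isinstance(dist, FrequencyDistribution):
        return dist.counts
    return np.asarray(dist, dtype=float)


def lorenz_curve(dist) -> LorenzCurve:
    x = np.sort(_as_counts(dist))
    if x.size == 0 or x.sum() <= 0:
        raise DegenerateDistributionError("Lorenz curve needs a positive total")
    m = x.size
    F = np.arange(m + 1) / m
    L = np.concatenate(([0.0], np.cumsum(x) / x.sum()))
    return LorenzCurve(F, L)


@dataclass
class GiniResult:
    gini: float
    method: str


def gini(dist, method: str = "lorenz_trapezoid") -> GiniResult:
    """Gini coefficient of the keyword-frequency distribution.

    ``lorenz_trapezoid`` applies ``2 (1/2 - ∫ L)`` to the trapezoid-
    integrated empirical Lorenz curve; ``pairwise`` is the mean-absolute-
    difference population estimator.  The two agree to numerical precision.
    """
    x = _as_counts(dist).astype(float)
    if x.size == 0 or x.sum() <= 0:
        raise DegenerateDistributionError("Gini needs a positive total")
    if method == "lorenz_trapezoid":
        curve = lorenz_curve(x)
        area = np.trapezoid(curve.L, curve.F)
        g = 2.0 * (0.5 - area)
    elif method == "pairwise":
        m = x.size
        g = float(np.abs(x[:, None] - x[None, :]).sum() / (2 * m * m * x.mean()))
    else:
        raise ValueError(f"unknown Gini method {method!r}")
    return GiniResult(float(g), method)


@dataclass
class ZTestResult:
    """Pooled two-proportion z-test; ``z`` keeps the sign of p1 - p2."""

    z: float
    p_value: float
    k1: int
    n1: int
    k2: int
    n2: int


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> ZTestResult:
    """Two-sided pooled z-test for a difference of proportions.

    z = (p1 - p2) / sqrt(p̂(1-p̂)(1/n1 + 1/n2)) with the pooled
    p̂ = (k1+k2)/(n1+n2); undefined when the pooled proportion is 0 or 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedStatisticError("pooled proportion is degenerate (0 or 1)")
    z, p = proportions_ztest(np.array([k1, k2]), np.array([n1, n2]))
    return ZTestResult(float(z), float(p), k1, n1, k2, n2)


# ---------------------------------------------------------------------- #
# combined report


@dataclass
class LongtailReport:
    """Stratified long-tail summary with pairwise z-tests.

    ``frame`` has one row per stratum (Hx, Px, pos, neg, total) and columns
    for keyword counts, threshold counts/percentages, annotation totals,
    top 1/10/20% segment counts and percentage shares, and the Gini
    coefficient.  ``ztests`` holds the Hx-vs-Px and pos-vs-neg comparisons
    on the same counts (NaN where the pooled test is undefined).
    """

    frame: pd.DataFrame
    ztests: pd.DataFrame


def _stratum_row(dist: FrequencyDistribution) -> dict:
    th = threshold_counts(dist)
    row = {
        "n_uk": dist.n_keywords,
        "n_ge4": th.n_ge4,
        "pct_ge4": th.pct_ge4,
        "n_eq1": th.n_eq1,
        "pct_eq1": th.pct_eq1,
        "n_ak": dist.total,
    }
    for pct in (1, 10, 20):
        if dist.n_keywords and dist.total:
            _, s = top_segment(dist, pct)
            row[f"top{pct}_n"] = s
            row[f"top{pct}_pct"] = percentage(s, dist.total, 1)
        else:
            row[f"top{pct}_n"] = 0
            row[f"top{pct}_pct"] = float("nan")
    row["gini"] = (
        gini(dist).gini if dist.total > 0 else float("nan")
    )
    return row


def longtail_report(corpus: Corpus) -> LongtailReport:
    """Table of long-tail diagnostics across the five strata."""
    dists = {s: frequency_distribution(corpus, s) for s in STRATA}
    frame = pd.DataFrame({s: _stratum_row(d) for s, d in dists.items()}).T

    comparisons = [("Hx", "Px"), ("pos", "neg")]
    metrics = {
        "ge4": ("n_ge4", "n_uk"),
        "eq1": ("n_eq1", "n_uk"),
        "top1": ("top1_n", "n_ak"),
        "top10": ("top10_n", "n_ak"),
        "top20": ("top20_n", "n_ak"),
    }
    rows = {}
    for a, b in comparisons:
        rec = {}
        for name, (kcol, ncol) in metrics.items():
            try:
                zt = two_proportion_z(
                    int(frame.loc[a, kcol]), int(frame.loc[a, ncol]),
                    int(frame.loc[b, kcol]), int(frame.loc[b, ncol]),
                )
                rec[f"{name}_z"], rec[f"{name}_p"] = zt.z, zt.p_value
            except (UndefinedStatisticError, ValueError):
                rec[f"{name}_z"] = rec[f"{name}_p"] = float("nan")
        rows[f"{a}_vs_{b}"] = rec
    return LongtailReport(frame, pd.DataFrame(rows).T)


# ---------------------------------------------------------------------- #
# plots


def plot_histogram(dist: FrequencyDistribution, ax=None):
    """Rank-frequency histogram of a stratum (descending)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(np.arange(1, dist.n_keywords + 1), dist.counts, width=1.0)
    ax.set_xlabel("keyword rank")
    ax.set_ylabel("annotation count")
    ax.set_title(f"Keyword frequencies ({dist.stratum})")
    return ax


def plot_lorenz(dists: Sequence[FrequencyDistribution], ax=None):
    """Lorenz curves of one or more strata against the equality diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="equality")
    for dist in dists:
        c = lorenz_curve(dist)
        g = gini(dist).gini
        ax.plot(c.F, c.L, label=f"{dist.stratum} (G={g:.3f})")
    ax.set_xlabel("cumulative fraction of keywords")
    ax.set_ylabel("cumulative share of annotations")
    ax.legend()
    return ax
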