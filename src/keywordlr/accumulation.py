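"""Accumulation curves and growth-curve regression.

As cases are added to a corpus, three cumulative series grow: the total
number of annotations, the number of distinct keywords seen so far, and
the number of distinct diagnoses.  Annotation totals grow linearly; the
vocabulary series decelerate, consistent with the closure property of a
clinical sublanguage (a bounded specialist lexicon).  Four model families
capture this:

====================  =============================  ===================
model                 equation                       fitting scale
====================  =============================  ===================
linear                y = a x + b                    original
logarithmic           y = a ln x + b                 original
power                 ln y = a ln x + b              log-log
power_plus_constant   y = a x^b + c                  original (nonlinear)
====================  =============================  ===================

The first three reduce to ordinary least squares on transformed
coordinates; the power+constant family is fit by damped nonlinear least
squares initialised from the log-log power fit.  R² is reported on the
model's own fitting scale (1 - RSS/TSS with the corrected total sum of
squares), so the power model's R² is a log-log quantity.  Fitted models
extrapolate to theoretical case counts (10^1..10^5) to project vocabulary
growth far beyond the observed corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .corpus import Corpus
from ._util import round_half_away_vec

__all__ = [
    "AccumulationCurves",
    "RegressionFit",
    "GrowthCurveModel",
    "ExtrapolationTable",
    "accumulation_curves",
    "fit_linear",
    "fit_logarithmic",
    "fit_power",
    "fit_power_plus_constant",
    "select_best_model",
    "extrapolate",
]

MODEL_N_PARAMS = {
    "linear": 2,
    "logarithmic": 2,
    "power": 2,
    "power_plus_constant": 3,
}


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (e.g. constant x)."""


class DomainError(ValueError):
    """Input outside the model's domain (non-positive x or y)."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit did not converge; carries the starting point used."""

    def __init__(self, message: str, p0: Sequence[float]):
        super().__init__(message)
        self.p0 = tuple(p0)


@dataclass
class AccumulationCurves:
    """Cumulative annotation / keyword / diagnosis counts per case index.

    ``x`` runs 1..N; in ``permuted`` mode the three series are averaged over
    seeded case-order shuffles (rarefaction-style), so they are fractional,
    while the endpoints always equal the corpus totals.
    """

    x: np.ndarray
    annotated: np.ndarray
    unique_keywords: np.ndarray
    diagnoses: np.ndarray
    mode: str
    replicates: int = 1
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cases": self.x,
                "annotated_keywords": self.annotated,
                "unique_keywords": self.unique_keywords,
                "diagnoses": self.diagnoses,
            }
        )


def _walk(order, ann_counts, kw_sets, dx_ids, n_kw, n_dx):
    ak = np.empty(len(order))
    uk = np.empty(len(order))
    dx = np.empty(len(order))
    seen_kw = np.zeros(n_kw, dtype=bool)
    seen_dx = np.zeros(n_dx, dtype=bool)
    tot_ak = tot_uk = tot_dx = 0
    for i, ci in enumerate(order):
        tot_ak += ann_counts[ci]
        kws = kw_sets[ci]
        fresh = ~seen_kw[kws]
        tot_uk += int(fresh.sum())
        seen_kw[kws[fresh]] = True
        if not seen_dx[dx_ids[ci]]:
            seen_dx[dx_ids[ci]] = True
            tot_dx += 1
        ak[i], uk[i], dx[i] = tot_ak, tot_uk, tot_dx
    return ak, uk, dx


def accumulation_curves(
    corpus: Corpus,
    mode: str = "input_order",
    replicates: int = 1,
    seed: int | None = None,
) -> AccumulationCurves:
    """Cumulative appearance curves over the corpus's cases.

    ``input_order`` walks the cases as stored; ``permuted`` averages the
    series over ``replicates`` random case orders, removing any dependence
    on the (often arbitrary) storage order.
    """
    if corpus.n_cases == 0:
        raise ValueError("accumulation curves need at least one case")
    if mode not in ("input_order", "permuted"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "permuted" and replicates < 1:
        raise ValueError("permuted mode needs replicates >= 1")

    case_ids = corpus.cases["case_id"].tolist()
    kw_index = {k: i for i, k in enumerate(corpus.keywords)}
    dx_index = {d: i for i, d in enumerate(corpus.diagnoses)}
    by_case = dict(tuple(corpus.annotations.groupby("case_id", sort=False)))
    kw_sets = []
    ann_counts = []
    for cid in case_ids:
        grp = by_case.get(cid)
        if grp is None:
            kw_sets.append(np.empty(0, dtype=int))
            ann_counts.append(0)
        else:
            kw_sets.append(np.array([kw_index[k] for k in grp["keyword"]], dtype=int))
            ann_counts.append(len(grp))
    dx_ids = np.array([dx_index[d] for d in corpus.cases["diagnosis"]], dtype=int)
    n = corpus.n_cases
    x = np.arange(1, n + 1)

    if mode == "input_order":
        ak, uk, dx = _walk(
            np.arange(n), ann_counts, kw_sets, dx_ids, len(kw_index), len(dx_index)
        )
        return AccumulationCurves(x, ak, uk, dx, mode)

    rng = np.random.default_rng(seed)
    acc = np.zeros((3, n))
    for _ in range(replicates):
        order = rng.permutation(n)
        ak, uk, dx = _walk(
            order, ann_counts, kw_sets, dx_ids, len(kw_index), len(dx_index)
        )
        acc += np.vstack([ak, uk, dx])
    acc /= replicates
    return AccumulationCurves(x, acc[0], acc[1], acc[2], mode, replicates, seed)


# ---------------------------------------------------------------------- #
# model / results


@dataclass
class RegressionFit:
    """Fitted growth-curve model (results object).

    ``params`` maps parameter names (``a``, ``b`` and, for the
    power+constant family, ``c``) to estimates; ``bse`` to standard errors.
    ``rsquared`` is computed on the model's fitting scale — log-log for the
    power family, original scale otherwise.
    """

    model: str
    params: dict[str, float]
    bse: dict[str, float]
    rsquared: float
    nobs: int
    scale_note: str = "original scale"

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model]

    def predict(self, x) -> np.ndarray:
        """Evaluate the fitted curve at case counts ``x`` (original scale)."""
        x = np.asarray(x, dtype=float)
        a, b = self.params["a"], self.params["b"]
        if self.model == "linear":
            return a * x + b
        if self.model == "logarithmic":
            if (x <= 0).any():
                raise DomainError("logarithmic model needs x > 0")
            return a * np.log(x) + b
        if self.model == "power":
            if (x <= 0).any():
                raise DomainError("power model needs x > 0")
            return np.exp(b) * x ** a
        if self.model == "power_plus_constant":
            return a * x ** b + self.params["c"]
        raise ValueError(f"unknown model {self.model!r}")

    def summary(self) -> str:
        lines = [
            "Growth-curve regression results",
            "=" * 46,
            f"model:        {self.model}",
            f"observations: {self.nobs}",
            f"R-squared:    {self.rsquared:.4f}  ({self.scale_note})",
            "-" * 46,
            f"{'param':>6} {'estimate':>14} {'std err':>14}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:>6} {val:>14.6g} {self.bse.get(name, float('nan')):>14.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)


class GrowthCurveModel:
    """Growth-curve model for one accumulation series.

    Parameters
    ----------
    x, y
        Case counts (1..N) and the cumulative series to model.

    ``fit(model=...)`` returns a :class:`RegressionFit`; ``fit_all()``
    fits every family and returns them keyed by name.
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def fit(self, model: str = "power_plus_constant", **kwargs) -> RegressionFit:
        if model == "linear":
            return self._fit_ols(self.x, self.y, "linear", "original scale")
        if model == "logarithmic":
            if (self.x <= 0).any():
                raise DomainError("logarithmic fit needs x > 0")
            return self._fit_ols(np.log(self.x), self.y, "logarithmic", "original scale")
        if model == "power":
            self._require_positive()
            return self._fit_ols(
                np.log(self.x), np.log(self.y), "power", "log-log scale"
            )
        if model == "power_plus_constant":
            return self._fit_power_plus_constant(**kwargs)
        raise ValueError(f"unknown model {model!r}")

    def fit_all(self, **kwargs) -> dict[str, RegressionFit]:
        return {m: self.fit(m, **({} if m != "power_plus_constant" else kwargs))
                for m in MODEL_N_PARAMS}

    # -- internals ----------------------------------------------------- #

    def _require_positive(self) -> None:
        if (self.x <= 0).any():
            bad = int(np.argmax(self.x <= 0))
            raise DomainError(f"power fit needs x > 0 (offending index {bad})")
        if (self.y <= 0).any():
            bad = int(np.argmax(self.y <= 0))
            raise DomainError(f"power fit needs y > 0 (offending index {bad})")

    def _fit_ols(self, xt, yt, name, scale_note) -> RegressionFit:
        if len(xt) < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(xt) == 0:
            raise SingularDesignError("x is constant after transformation")
        res = sm.OLS(yt, sm.add_constant(xt)).fit()
        b, a = res.params  # [intercept, slope]
        se_b, se_a = res.bse
        return RegressionFit(
            model=name,
            params={"a": float(a), "b": float(b)},
            bse={"a": float(se_a), "b": float(se_b)},
            rsquared=float(res.rsquared),
            nobs=len(xt),
            scale_note=scale_note,
        )

    def _fit_power_plus_constant(
        self, tol: float = 1e-8, max_iter: int = 10_000
    ) -> RegressionFit:
        x, y = self.x, self.y
        if len(x) < 4:
            raise ValueError("power+constant needs at least 4 points")
        if (x <= 0).any():
            raise DomainError("power+constant fit needs x > 0")
        # warm start from the log-log power fit with c0 = 0
        if (y > 0).all() and np.ptp(x) > 0:
            loglog = self.fit("power")
            p0 = [float(np.exp(loglog.params["b"])), float(loglog.params["a"]), 0.0]
        else:
            p0 = [1.0, 1.0, float(np.min(y))]

        def f(x_, a, b, c):
            return a * np.power(x_, b) + c

        try:
            popt, pcov = curve_fit(
                f, x, y, p0=p0, maxfev=max_iter, xtol=tol, ftol=tol
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"power+constant fit did not converge within {max_iter} "
                f"evaluations (started from {p0})",
                p0,
            ) from exc
        resid = y - f(x, *popt)
        tss = float(((y - y.mean()) ** 2).sum())
        rsq = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else float("nan")
        bse = np.sqrt(np.diag(pcov))
        return RegressionFit(
            model="power_plus_constant",
            params={"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
            bse={"a": float(bse[0]), "b": float(bse[1]), "c": float(bse[2])},
            rsquared=rsq,
            nobs=len(x),
        )


# module-level conveniences -------------------------------------------- #


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares for y = a x + b."""
    return GrowthCurveModel(x, y).fit("linear")


def fit_logarithmic(x, y) -> RegressionFit:
    """OLS of y on ln x (y = a ln x + b)."""
    return GrowthCurveModel(x, y).fit("logarithmic")


def fit_power(x, y) -> RegressionFit:
    """OLS of ln y on ln x (ln y = a ln x + b); R² on the log-log scale."""
    return GrowthCurveModel(x, y).fit("power")


def fit_power_plus_constant(x, y, tol: float = 1e-8, max_iter: int = 10_000) -> RegressionFit:
    """Nonlinear least squares for y = a x^b + c."""
    return GrowthCurveModel(x, y).fit("power_plus_constant", tol=tol, max_iter=max_iter)


def select_best_model(fits: Iterable[RegressionFit]) -> RegressionFit:
    """The fit with the highest R²; exact ties go to fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    return max(fits, key=lambda f: (f.rsquared, -f.n_params))


@dataclass
class ExtrapolationTable:
    """Model predictions at theoretical case counts.

    ``rounded`` holds integers (halves away from zero), matching how
    projected vocabulary sizes are reported; ``raw`` keeps the unrounded
    values.  No clamping: a linear model evaluated left of its fitted range
    may go negative, which is reported as-is.
    """

    model: str
    case_counts: np.ndarray
    raw: np.ndarray
    rounded: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cases": self.case_counts, "raw": self.raw,
             "predicted": self.rounded.astype(int)}
        )


def extrapolate(fit: RegressionFit, case_counts) -> ExtrapolationTable:
    """Evaluate a fitted model at the requested case counts."""
    case_counts = np.asarray(case_counts, dtype=float)
    raw = fit.predict(case_counts)
    rounded = round_half_away_vec(raw, 0)
    return ExtrapolationTable(fit.model, case_counts, raw, rounded)
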