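"""Full-analysis orchestration and report rendering.

``run_full_analysis`` chains the stages — corpus summary, cross table with
calculability accounting and significance screening, long-tail diagnostics,
accumulation curves with the four-family regression and extrapolation —
into one :class:`AnalysisReport` that is deterministic given the corpus and
configuration, and serialisable to JSON or Markdown.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corpus import Corpus, corpus_summary, read_corpus
from .crosstable import (
    build_cross_table,
    calculability_summary,
    significant_combinations,
)
from .longtail import longtail_report
from .accumulation import (
    GrowthCurveModel,
    accumulation_curves,
    extrapolate,
    select_best_model,
)

logger = logging.getLogger("keywordlr.report")

DEFAULT_EXTRAPOLATION_GRID = (10, 100, 1_000, 10_000, 100_000)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    alpha: float = 0.05
    ci_method: str = "auto"
    chi2_correction: bool = False
    multiplicity: str | None = None
    accumulation_mode: str = "input_order"
    accumulation_replicates: int = 100
    seed: int = 0
    extrapolation_grid: tuple[int, ...] = DEFAULT_EXTRAPOLATION_GRID

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(g <= 0 for g in self.extrapolation_grid):
            raise ValueError("extrapolation grid must be positive")

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Aggregated results of the full pipeline (all recomputable)."""

    config: RunConfig
    corpus_summary: dict
    calculability: dict
    significant: list[dict]
    longtail: dict
    fits: dict
    extrapolations: dict
    provenance: dict
    warnings: list[str] = field(default_factory=list)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_full_analysis(corpus: Corpus, config: RunConfig | None = None) -> AnalysisReport:
    """Run corpus -> cross table -> long tail -> accumulation in order."""
    config = config or RunConfig()
    warnings: list[str] = []

    logger.info("stage corpus: %d cases, %d annotations", corpus.n_cases,
                corpus.n_annotations)
    if corpus.n_collapsed_duplicates:
        warnings.append(
            f"{corpus.n_collapsed_duplicates} duplicate annotation rows collapsed"
        )
    summary = corpus_summary(corpus)
    summary_doc = {
        "n_cases": summary.n_cases,
        "unique_keywords": summary.unique_keywords.to_dict(),
        "annotated_keywords": summary.annotated_keywords.to_dict(),
        "ak_per_case": summary.ak_per_case.to_dict(),
    }

    try:
        table = build_cross_table(corpus)
        calc = calculability_summary(table)
        sig = significant_combinations(
            table,
            alpha=config.alpha,
            ci_method=config.ci_method,
            correction=config.chi2_correction,
            multiplicity=config.multiplicity,
        )
        calc_doc = {
            "counts": calc.counts.to_dict(),
            "percents": calc.percents.to_dict(),
            "totals": calc.totals,
            "n_cells": table.n_cells,
        }
        sig_doc = [
            {"diagnosis": s.diagnosis, "keyword": s.keyword,
             "section": s.section, **s.opchar.as_dict()}
            for s in sig
        ]
        logger.info("stage crosstable: %d cells, %d significant",
                    table.n_cells, len(sig))
    except ValueError as exc:
        warnings.append(f"crosstable stage degenerate: {exc}")
        calc_doc, sig_doc = {}, []

    lt = longtail_report(corpus)
    lt_doc = {"strata": lt.frame.to_dict(), "ztests": lt.ztests.to_dict()}
    logger.info("stage longtail: %d strata", len(lt.frame))

    fits_doc: dict = {}
    extrap_doc: dict = {}
    series: dict = {}
    try:
        curves = accumulation_curves(
            corpus,
            mode=config.accumulation_mode,
            replicates=config.accumulation_replicates,
            seed=config.seed,
        )
        series = {
            "annotated_keyword": curves.annotated,
            "unique_keyword": curves.unique_keywords,
            "diagnosis": curves.diagnoses,
        }
    except ValueError as exc:
        warnings.append(f"accumulation stage degenerate: {exc}")
    for name, y in series.items():
        model = GrowthCurveModel(curves.x, y)
        try:
            fits = model.fit_all()
        except Exception as exc:  # degenerate series (e.g. 1 case)
            warnings.append(f"accumulation stage: {name} not fittable: {exc}")
            continue
        best = select_best_model(fits.values())
        fits_doc[name] = {
            m: {"params": f.params, "bse": f.bse, "rsquared": f.rsquared}
            for m, f in fits.items()
        }
        fits_doc[name]["best"] = best.model
        tab = extrapolate(best, np.asarray(config.extrapolation_grid, dtype=float))
        extrap_doc[name] = {
            "model": best.model,
            "cases": list(config.extrapolation_grid),
            "predicted": [int(v) for v in tab.rounded],
            "raw": list(tab.raw),
        }
    logger.info("stage accumulation: fitted %d series", len(fits_doc))

    provenance = {
        "package": "keywordlr",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
    }
    return AnalysisReport(
        config=config,
        corpus_summary=_jsonable(summary_doc),
        calculability=_jsonable(calc_doc),
        significant=_jsonable(sig_doc),
        longtail=_jsonable(lt_doc),
        fits=_jsonable(fits_doc),
        extrapolations=_jsonable(extrap_doc),
        provenance=provenance,
        warnings=warnings,
    )


# ---------------------------------------------------------------------- #
# rendering


def _md_table(header: list[str], rows: list[list]) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    out = ["| " + " | ".join(header) + " |",
           "| " + " | ".join("---" for _ in header) + " |"]
    for row in rows:
        out.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(out)


def render_report(report: AnalysisReport, style: str = "json") -> str:
    """Serialise a report as schema-stable JSON or readable Markdown."""
    if style == "json":
        doc = dataclasses.asdict(report)
        doc["config"] = dataclasses.asdict(report.config)
        return json.dumps(_jsonable(doc), sort_keys=True, indent=1) + "\n"
    if style != "markdown":
        raise ValueError(f"unknown style {style!r}")

    parts = [f"# Analysis report (keywordlr {report.provenance['version']})", ""]
    parts.append(f"Seed {report.provenance['seed']}, "
                 f"config hash `{report.provenance['config_hash']}`.")
    if report.warnings:
        parts += ["", "## Warnings", ""]
        parts += [f"- {w}" for w in report.warnings]

    cs = report.corpus_summary
    parts += ["", "## Corpus summary", ""]
    uk, ak = cs.get("unique_keywords", {}), cs.get("annotated_keywords", {})
    if uk:
        rows = [
            [row, uk["Hx"][row], uk["Px"][row], uk["total"][row],
             ak["Hx"][row], ak["Px"][row], ak["total"][row]]
            for row in ("pos", "neg", "total")
        ]
        parts.append(_md_table(
            ["stratum", "UK Hx", "UK Px", "UK total", "AK Hx", "AK Px", "AK total"],
            rows,
        ))
    parts.append(f"\nCases: {cs.get('n_cases', 0)}")

    if report.calculability:
        parts += ["", "## Calculable combinations", ""]
        counts = report.calculability["counts"]
        pct = report.calculability["percents"]
        metrics = list(next(iter(counts.values())).keys())
        rows = [
            [m] + [f"{counts[s][m]} ({pct[s][m]}%)" for s in ("Hx", "Px", "total")]
            for m in metrics
        ]
        parts.append(_md_table(["metric", "Hx", "Px", "total"], rows))
        parts.append(f"\nCross-table cells: {report.calculability.get('n_cells')}")

    parts += ["", "## Significant combinations", ""]
    if report.significant:
        rows = [
            [s["section"], s["keyword"], s["diagnosis"],
             s["sensitivity"], s["specificity"], s["plr"], s["nlr"], s["p"]]
            for s in report.significant
        ]
        parts.append(_md_table(
            ["section", "keyword", "diagnosis", "sens", "spec", "LR+", "LR-", "p"],
            rows,
        ))
    else:
        parts.append("(none)")

    lt = report.longtail.get("strata", {})
    if lt:
        parts += ["", "## Long-tail diagnostics", ""]
        strata = list(next(iter(lt.values())).keys())
        cols = ["n_uk", "n_ge4", "pct_ge4", "n_eq1", "pct_eq1", "n_ak",
                "top1_pct", "top10_pct", "top20_pct", "gini"]
        rows = [[s] + [lt[c][s] for c in cols] for s in strata]
        parts.append(_md_table(["stratum"] + cols, rows))

    if report.fits:
        parts += ["", "## Growth-curve fits", ""]
        rows = []
        for series, fits in report.fits.items():
            best = fits["best"]
            for m, f in fits.items():
                if m == "best":
                    continue
                p = f["params"]
                rows.append([
                    series, m + (" *" if m == best else ""),
                    p.get("a"), p.get("b"), p.get("c", ""), f["rsquared"],
                ])
        parts.append(_md_table(["series", "model", "a", "b", "c", "R2"], rows))

    if report.extrapolations:
        parts += ["", "## Theoretical values", ""]
        any_e = next(iter(report.extrapolations.values()))
        header = ["series", "model"] + [str(c) for c in any_e["cases"]]
        rows = [
            [series, e["model"]] + e["predicted"]
            for series, e in report.extrapolations.items()
        ]
        parts.append(_md_table(header, rows))

    return "\n".join(parts) + "\n"


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write JSON and Markdown renderings; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for style, name in (("json", "report.json"), ("markdown", "report.md")):
        p = out_dir / name
        p.write_text(render_report(report, style), encoding="utf-8")
        paths[style] = p
    return paths
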