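"""Data model and I/O for annotated-keyword corpora.

A corpus is a collection of clinical cases.  Each case carries an ICHD-II
diagnosis code and a set of *annotated keywords* (AKs): polarity-tagged
occurrences of *unique keywords* (UKs) that were found asserted (``pos``) or
negated (``neg``) in the record text.  Every unique keyword belongs to exactly
one section: history (``Hx``) or physical examination / tests (``Px``).
Keywords that never appear in a case are null for that case and are simply
absent from its annotation list.

Two plain-text serialisations are supported: a five-column TSV with one row
per annotation, and a JSON dialect with one object per case.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._util import per_case_rate, round_half_away

logger = logging.getLogger("keywordlr.corpus")

SECTIONS = ("Hx", "Px")
POLARITIES = ("pos", "neg")
ANNOTATION_COLUMNS = ["case_id", "diagnosis", "keyword", "section", "polarity"]


class CorpusError(Exception):
    """Base class for corpus ingestion problems."""


class CorpusParseError(CorpusError):
    """Structurally malformed input (bad columns, empty fields)."""


class CorpusValidationError(CorpusError):
    """Well-formed input that violates a corpus invariant."""


@dataclass(frozen=True)
class AnnotatedKeyword:
    """One polarity-tagged keyword occurrence attached to a case."""

    case_id: str
    keyword: str
    section: str
    polarity: str

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise CorpusValidationError(
                f"section must be one of {SECTIONS}, got {self.section!r}"
            )
        if self.polarity not in POLARITIES:
            raise CorpusValidationError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )


@dataclass(frozen=True)
class KeywordInventoryEntry:
    """A unique keyword and the section it belongs to."""

    keyword: str
    section: str


@dataclass
class CaseRecord:
    """A case: opaque id, ICHD-II diagnosis code, and its annotations."""

    case_id: str
    diagnosis: str
    annotations: tuple[AnnotatedKeyword, ...] = ()

    def __post_init__(self) -> None:
        if not self.diagnosis:
            raise CorpusValidationError(f"case {self.case_id!r} has empty diagnosis")
        for ak in self.annotations:
            if ak.case_id != self.case_id:
                raise CorpusValidationError(
                    f"annotation case_id {ak.case_id!r} != record {self.case_id!r}"
                )


class Corpus:
    """Validated, deduplicated annotated-keyword corpus.

    Parameters
    ----------
    cases
        DataFrame with columns ``case_id``, ``diagnosis``; row order is the
        input case order and is preserved throughout.
    annotations
        DataFrame with columns ``case_id``, ``keyword``, ``section``,
        ``polarity``; at most one row per (case_id, keyword).

    The keyword inventory (keyword -> section) is derived from the
    annotations; a keyword appearing under two sections is rejected.
    """

    def __init__(self, cases: pd.DataFrame, annotations: pd.DataFrame) -> None:
        cases = cases.reset_index(drop=True)[["case_id", "diagnosis"]].astype(str)
        ann = annotations.reset_index(drop=True)[
            ["case_id", "keyword", "section", "polarity"]
        ].astype(str)

        if cases["case_id"].duplicated().any():
            dups = cases.loc[cases["case_id"].duplicated(), "case_id"].tolist()
            raise CorpusValidationError(f"duplicate case ids: {dups[:5]}")
        if (cases["diagnosis"] == "").any():
            raise CorpusValidationError("empty diagnosis code")
        bad_sec = ~ann["section"].isin(SECTIONS)
        if bad_sec.any():
            tok = ann.loc[bad_sec, "section"].iloc[0]
            raise CorpusValidationError(f"unknown section token {tok!r}")
        bad_pol = ~ann["polarity"].isin(POLARITIES)
        if bad_pol.any():
            tok = ann.loc[bad_pol, "polarity"].iloc[0]
            raise CorpusValidationError(f"unknown polarity token {tok!r}")
        unknown = ~ann["case_id"].isin(set(cases["case_id"]))
        if unknown.any():
            raise CorpusValidationError(
                f"annotation refers to unknown case {ann.loc[unknown, 'case_id'].iloc[0]!r}"
            )
        if ann.duplicated(["case_id", "keyword"]).any():
            raise CorpusValidationError(
                "multiple annotations per (case, keyword); use Corpus.from_frame "
                "to apply the deduplication rule"
            )

        sec_per_kw = ann.groupby("keyword")["section"].nunique()
        offenders = sec_per_kw[sec_per_kw > 1].index.tolist()
        if offenders:
            raise CorpusValidationError(
                f"keywords tagged with both sections: {offenders}"
            )

        self.cases = cases
        self.annotations = ann
        self.n_collapsed_duplicates = 0
        self.n_polarity_conflicts = 0
        inv = (
            ann.drop_duplicates("keyword")[["keyword", "section"]]
            .sort_values("keyword", kind="stable")
            .reset_index(drop=True)
        )
        self._inventory = inv

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Corpus":
        """Build a corpus from a long table (one row per annotation).

        Applies the ingestion rules: repeated (case, keyword) rows collapse to
        one annotation; if the repeats disagree on polarity the positive one
        wins (an asserted finding anywhere in a record outweighs a negation).
        Both events are logged and counted on the returned corpus.
        """
        missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
        if missing:
            raise CorpusParseError(f"missing required columns: {missing}")
        frame = frame.reset_index(drop=True).astype(str)

        cases = frame.drop_duplicates("case_id")[["case_id", "diagnosis"]]
        multi_dx = frame.groupby("case_id")["diagnosis"].nunique()
        if (multi_dx > 1).any():
            bad = multi_dx[multi_dx > 1].index.tolist()
            raise CorpusValidationError(f"cases with conflicting diagnoses: {bad[:5]}")

        ann = frame[["case_id", "keyword", "section", "polarity"]].copy()
        n_collapsed = 0
        n_conflicts = 0
        dup_mask = ann.duplicated(["case_id", "keyword"], keep=False)
        if dup_mask.any():
            dup = ann[dup_mask]
            n_collapsed = int(dup_mask.sum() - dup[["case_id", "keyword"]].drop_duplicates().shape[0])
            pol_n = dup.groupby(["case_id", "keyword"])["polarity"].nunique()
            n_conflicts = int((pol_n > 1).sum())
            # positive-polarity precedence, first occurrence keeps its position
            order = np.arange(len(ann))
            ann = ann.assign(_order=order)
            grouped = ann.groupby(["case_id", "keyword"], sort=False).agg(
                section=("section", "first"),
                polarity=("polarity", lambda s: "pos" if (s == "pos").any() else "neg"),
                _order=("_order", "min"),
            )
            ann = (
                grouped.reset_index()
                .sort_values("_order", kind="stable")
                .drop(columns="_order")
                .reset_index(drop=True)
            )
            if n_collapsed:
                logger.warning(
                    "collapsed %d duplicate (case, keyword) annotation rows "
                    "(%d with conflicting polarity; positive kept)",
                    n_collapsed,
                    n_conflicts,
                )
        corpus = cls(cases, ann)
        corpus.n_collapsed_duplicates = n_collapsed
        corpus.n_polarity_conflicts = n_conflicts
        return corpus

    @classmethod
    def from_cases(cls, records: Iterable[CaseRecord]) -> "Corpus":
        records = list(records)
        cases = pd.DataFrame(
            {"case_id": [r.case_id for r in records],
             "diagnosis": [r.diagnosis for r in records]}
        )
        rows = [
            (ak.case_id, ak.keyword, ak.section, ak.polarity)
            for r in records
            for ak in r.annotations
        ]
        ann = pd.DataFrame(rows, columns=["case_id", "keyword", "section", "polarity"])
        return cls(cases, ann)

    # ------------------------------------------------------------------ #
    # views

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    @property
    def inventory(self) -> pd.DataFrame:
        """Keyword inventory: columns ``keyword``, ``section`` (sorted)."""
        return self._inventory

    @property
    def n_keywords(self) -> int:
        return len(self._inventory)

    @property
    def keywords(self) -> list[str]:
        return self._inventory["keyword"].tolist()

    @property
    def diagnoses(self) -> list[str]:
        """Distinct diagnosis codes, sorted lexicographically."""
        return sorted(self.cases["diagnosis"].unique())

    def section_of(self) -> dict[str, str]:
        return dict(zip(self._inventory["keyword"], self._inventory["section"]))

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per annotation with the case diagnosis joined."""
        out = self.annotations.merge(self.cases, on="case_id", how="left")
        return out[ANNOTATION_COLUMNS]

    def case_records(self) -> Iterator[CaseRecord]:
        by_case = {
            cid: grp for cid, grp in self.annotations.groupby("case_id", sort=False)
        }
        for _, row in self.cases.iterrows():
            grp = by_case.get(row.case_id)
            aks: tuple[AnnotatedKeyword, ...] = ()
            if grp is not None:
                aks = tuple(
                    AnnotatedKeyword(r.case_id, r.keyword, r.section, r.polarity)
                    for r in grp.itertuples(index=False)
                )
            yield CaseRecord(row.case_id, row.diagnosis, aks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        if not self.cases.equals(other.cases):
            return False
        a = self.annotations.sort_values(["case_id", "keyword"], kind="stable")
        b = other.annotations.sort_values(["case_id", "keyword"], kind="stable")
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Corpus: {self.n_cases} cases, {len(self.diagnoses)} diagnoses, "
            f"{self.n_keywords} keywords, {self.n_annotations} annotations>"
        )


# ---------------------------------------------------------------------- #
# I/O


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "json":
        return "json"
    raise CorpusParseError(f"cannot infer format from suffix {path.suffix!r}")


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from TSV or JSON.

    TSV: UTF-8, tab-separated, header ``case_id diagnosis keyword section
    polarity``, tokens ``Hx|Px`` and ``pos|neg``, one row per annotation.
    JSON: ``{"cases": [{"case_id", "diagnosis", "annotations": [...]}]}``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "json":
        return _read_json(path)
    raise CorpusParseError(f"unknown format {fmt!r}")


def _read_tsv(path: Path) -> Corpus:
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.ParserError as exc:
        raise CorpusParseError(f"{path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusParseError(f"{path}: missing columns {missing}")
    frame = frame[ANNOTATION_COLUMNS]
    empty = (frame == "").any(axis=1)
    if empty.any():
        # +2: one for the header, one for 0- vs 1-based indexing
        line = int(empty.idxmax()) + 2
        raise CorpusParseError(f"{path}: empty field on line {line}")
    return Corpus.from_frame(frame)


def _read_json(path: Path) -> Corpus:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CorpusParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if not isinstance(doc, dict) or "cases" not in doc:
        raise CorpusParseError(f"{path}: expected top-level object with 'cases'")
    rows = []
    case_rows = []
    for i, case in enumerate(doc["cases"]):
        try:
            cid, dx = str(case["case_id"]), str(case["diagnosis"])
        except (TypeError, KeyError) as exc:
            raise CorpusParseError(f"{path}: case #{i} missing case_id/diagnosis") from exc
        case_rows.append((cid, dx))
        for ak in case.get("annotations", []):
            try:
                rows.append((cid, ak["keyword"], ak["section"], ak["polarity"]))
            except (TypeError, KeyError) as exc:
                raise CorpusParseError(
                    f"{path}: malformed annotation in case {cid!r}"
                ) from exc
    cases = pd.DataFrame(case_rows, columns=["case_id", "diagnosis"])
    ann = pd.DataFrame(rows, columns=["case_id", "keyword", "section", "polarity"])
    # route through from_frame for the dedup rule, then restore empty cases
    joined = ann.merge(cases, on="case_id")[ANNOTATION_COLUMNS]
    corpus = Corpus.from_frame(joined) if len(joined) else Corpus(cases.iloc[0:0], ann)
    if len(cases) != corpus.n_cases:
        out = Corpus(cases, corpus.annotations)
        out.n_collapsed_duplicates = corpus.n_collapsed_duplicates
        out.n_polarity_conflicts = corpus.n_polarity_conflicts
        return out
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus; ``read_corpus(write_corpus(c))`` round-trips.

    TSV carries one row per annotation, so a case without annotations cannot
    be represented there (a warning is logged); JSON preserves it.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        frame = corpus.to_frame()
        n_empty = corpus.n_cases - frame["case_id"].nunique()
        if n_empty:
            logger.warning(
                "TSV output drops %d case(s) without annotations", n_empty
            )
        frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
    elif fmt == "json":
        by_case = {
            cid: grp for cid, grp in corpus.annotations.groupby("case_id", sort=False)
        }
        cases = []
        for row in corpus.cases.itertuples(index=False):
            grp = by_case.get(row.case_id)
            anns = []
            if grp is not None:
                anns = [
                    {"keyword": r.keyword, "section": r.section, "polarity": r.polarity}
                    for r in grp.itertuples(index=False)
                ]
            cases.append(
                {"case_id": row.case_id, "diagnosis": row.diagnosis, "annotations": anns}
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"cases": cases}, fh, ensure_ascii=False, indent=1)
            fh.write("\n")
    else:
        raise CorpusParseError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------- #
# descriptive summary


@dataclass
class CorpusSummary:
    """Section x polarity breakdown of unique and annotated keywords.

    ``unique_keywords`` counts inventory entries with at least one annotation
    of the given polarity (a keyword annotated both ways counts in both rows,
    so rows need not sum to the total).  ``annotated_keywords`` counts
    annotations and is additive.  Per-case rates are raw (unrounded); the
    ``table()`` view applies the reporting precision (2 decimals for rates,
    1 for ratios).
    """

    n_cases: int
    unique_keywords: pd.DataFrame
    annotated_keywords: pd.DataFrame

    @property
    def ak_per_case(self) -> pd.DataFrame:
        if self.n_cases == 0:
            return self.annotated_keywords * float("nan")
        return self.annotated_keywords / self.n_cases

    def ratios(self) -> dict[str, pd.Series]:
        uk, ak = self.unique_keywords, self.annotated_keywords
        with np.errstate(divide="ignore", invalid="ignore"):
            return {
                "uk_hx_over_px": uk["Hx"] / uk["Px"],
                "uk_pos_over_neg": uk.loc["pos"] / uk.loc["neg"],
                "ak_hx_over_px": ak["Hx"] / ak["Px"],
                "ak_pos_over_neg": ak.loc["pos"] / ak.loc["neg"],
            }

    def table(self) -> pd.DataFrame:
        """Human-readable summary at the printed precision."""
        rows = []
        for pol in ("pos", "neg", "total"):
            rec = {"stratum": f"UK {pol}"}
            for sec in ("Hx", "Px", "total"):
                rec[sec] = int(self.unique_keywords.loc[pol, sec])
            rows.append(rec)
        for pol in ("pos", "neg", "total"):
            rec = {"stratum": f"AK {pol}"}
            for sec in ("Hx", "Px", "total"):
                n = int(self.annotated_keywords.loc[pol, sec])
                rate = per_case_rate(n, self.n_cases) if self.n_cases else float("nan")
                rec[sec] = f"{n} ({rate})"
            rows.append(rec)
        return pd.DataFrame(rows).set_index("stratum")


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Cross-classify unique/annotated keyword counts by section and polarity."""
    ann = corpus.annotations
    secs = ("Hx", "Px")
    pols = ("pos", "neg")

    uk = pd.DataFrame(0, index=[*pols, "total"], columns=[*secs, "total"], dtype=int)
    ak = uk.copy()
    for sec in secs:
        in_sec = ann[ann["section"] == sec]
        uk.loc["total", sec] = in_sec["keyword"].nunique()
        ak.loc["total", sec] = len(in_sec)
        for pol in pols:
            sub = in_sec[in_sec["polarity"] == pol]
            uk.loc[pol, sec] = sub["keyword"].nunique()
            ak.loc[pol, sec] = len(sub)
    for pol in pols:
        sub = ann[ann["polarity"] == pol]
        uk.loc[pol, "total"] = sub["keyword"].nunique()
        ak.loc[pol, "total"] = len(sub)
    uk.loc["total", "total"] = ann["keyword"].nunique()
    ak.loc["total", "total"] = len(ann)
    return CorpusSummary(corpus.n_cases, uk, ak)
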