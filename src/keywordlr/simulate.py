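"""Synthetic annotated-keyword corpus generator.

The generator emulates the statistical structure of an emergency-room
headache corpus: ~270 cases coded to 26 ICHD-II diagnoses with a strongly
skewed diagnosis mix, a keyword inventory split into history (Hx) and
examination (Px) sections, Zipf-like keyword popularity producing a
long-tailed annotation-frequency distribution (Gini around 0.7), and
section-specific positive/negative annotation rates (history findings are
mostly asserted; examination findings are mostly negated, reflecting
systematic checklist-style examination notes).

It does not emulate free text, annotator disagreement, or correlation
between keywords beyond the planted diagnosis-keyword associations; planted
associations exist so that downstream cross-table estimates can be checked
against known sensitivities and specificities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus

__all__ = [
    "PlantedAssociation",
    "SynthConfig",
    "default_config",
    "generate_corpus",
    "plant_association",
    "TABLE1_DIAGNOSIS_COUNTS",
]

# ICHD-II code -> number of cases in the 270-case diagnosis mix the defaults
# emulate (26 codes; "14" is the unresolved/other-headache bucket).
TABLE1_DIAGNOSIS_COUNTS: dict[str, int] = {
    "1": 36, "2": 35, "4": 19, "5.1": 27, "5.3": 1, "5.5": 1, "5.5.2": 2,
    "6.1.1": 1, "6.2.2": 1, "7.3.2": 1, "7.4": 1, "7.9": 1, "9.1.2": 4,
    "9.2.1": 6, "9.2.2": 30, "10.3": 6, "11.2": 1, "11.5": 7, "11.6": 1,
    "11.8": 2, "12.1": 2, "13.1": 1, "13.8": 2, "13.9": 1, "13.15": 8,
    "14": 73,
}

# Rank-popularity exponent calibrated once so that the realized total-stratum
# Gini coefficient of the default 270-case corpus is ~0.7 (see docs/methods.md).
DEFAULT_ZIPF_EXPONENT = 1.15


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PlantedAssociation:
    """A known diagnosis-keyword link injected into the corpus.

    Cases carrying ``diagnosis`` receive a positive annotation of ``keyword``
    with probability ``sensitivity`` and a negative one otherwise; cases
    without the diagnosis receive a negative annotation with probability
    ``specificity`` and a positive one otherwise.  Every case is therefore
    annotated for the keyword, so the downstream contingency cell estimates
    converge to the planted values.
    """

    diagnosis: str
    keyword: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus.

    ``mean_ak_per_case_*`` are the expected numbers of annotations per case
    and section (Poisson, truncated to the inventory size);
    ``p_positive_given_*`` the chance an emitted annotation is positive;
    ``zipf_exponent`` the rank-popularity exponent (keyword of popularity
    rank r is drawn with probability proportional to r^-s).
    """

    n_cases: int
    diagnosis_probs: dict[str, float]
    n_keywords_hx: int
    n_keywords_px: int
    zipf_exponent: float
    mean_ak_per_case_hx: float
    mean_ak_per_case_px: float
    p_positive_given_hx: float
    p_positive_given_px: float
    planted: tuple[PlantedAssociation, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be positive")
        if self.n_keywords_hx < 1 or self.n_keywords_px < 1:
            raise ConfigError("keyword inventory sizes must be positive")
        if self.zipf_exponent < 0:
            raise ConfigError("zipf_exponent must be non-negative")
        if self.mean_ak_per_case_hx <= 0 or self.mean_ak_per_case_px <= 0:
            raise ConfigError("mean annotations per case must be positive")
        total = sum(self.diagnosis_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"diagnosis_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.diagnosis_probs.values()):
            raise ConfigError("diagnosis probabilities must be non-negative")
        for name in ("p_positive_given_hx", "p_positive_given_px"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")

    # -- inventory ---------------------------------------------------- #

    def keyword_names(self, section: str) -> list[str]:
        n = self.n_keywords_hx if section == "Hx" else self.n_keywords_px
        prefix = section.lower()
        width = max(3, len(str(n)))
        return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]

    def inventory(self) -> pd.DataFrame:
        rows = [(k, "Hx") for k in self.keyword_names("Hx")]
        rows += [(k, "Px") for k in self.keyword_names("Px")]
        return pd.DataFrame(rows, columns=["keyword", "section"])

    # -- serialisation ------------------------------------------------ #

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["planted"] = [dataclasses.asdict(a) for a in self.planted]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        planted = tuple(PlantedAssociation(**a) for a in doc.pop("planted", []))
        return cls(planted=planted, **doc)


def default_config(seed: int = 0) -> SynthConfig:
    """Default study conditions: 270 cases, 26 diagnoses, 521+102 keywords.

    Rates are taken from the corpus structure the generator emulates:
    3,789/270 history and 3,115/270 examination annotations per case, with
    2,566/3,789 of history and 174/3,115 of examination annotations positive.
    """
    n = sum(TABLE1_DIAGNOSIS_COUNTS.values())
    probs = {code: c / n for code, c in TABLE1_DIAGNOSIS_COUNTS.items()}
    return SynthConfig(
        n_cases=270,
        diagnosis_probs=probs,
        n_keywords_hx=521,
        n_keywords_px=102,
        zipf_exponent=DEFAULT_ZIPF_EXPONENT,
        mean_ak_per_case_hx=3789 / 270,
        mean_ak_per_case_px=3115 / 270,
        p_positive_given_hx=2566 / 3789,
        p_positive_given_px=174 / 3115,
        seed=seed,
    )


def plant_association(config: SynthConfig, assoc: PlantedAssociation) -> SynthConfig:
    """Return a new config with ``assoc`` appended (original unmodified).

    If several associations name the same keyword, the one appended last
    governs its emission.
    """
    names = set(config.keyword_names("Hx")) | set(config.keyword_names("Px"))
    if assoc.keyword not in names:
        raise ConfigError(f"unknown keyword {assoc.keyword!r}")
    if assoc.diagnosis not in config.diagnosis_probs:
        raise ConfigError(f"unknown diagnosis {assoc.diagnosis!r}")
    return dataclasses.replace(config, planted=config.planted + (assoc,))


def _sample_section(
    rng: np.random.Generator,
    n_cases: int,
    n_keywords: int,
    mean: float,
    exponent: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-case keyword draws without replacement under a Zipf rank law.

    Returns (case_index, keyword_index) arrays.  Uses the Gumbel-top-k trick:
    adding i.i.d. Gumbel noise to log-weights and taking the k largest keys
    is equivalent to successive weighted sampling without replacement.
    """
    if mean > n_keywords:
        raise ConfigError(
            f"mean annotations per case ({mean}) exceeds inventory size ({n_keywords})"
        )
    k = np.minimum(rng.poisson(mean, size=n_cases), n_keywords)
    log_w = -exponent * np.log(np.arange(1, n_keywords + 1, dtype=float))
    keys = log_w[None, :] + rng.gumbel(size=(n_cases, n_keywords))
    order = np.argsort(-keys, axis=1, kind="stable")
    col = np.arange(n_keywords)[None, :]
    mask = col < k[:, None]
    case_idx = np.repeat(np.arange(n_cases), k)
    kw_idx = order[mask]
    return case_idx, kw_idx


def generate_corpus(config: SynthConfig) -> Corpus:
    """Draw a corpus from the configured generative model.

    Per case: a diagnosis from ``diagnosis_probs``; per section a truncated-
    Poisson number of annotations whose keywords are drawn without
    replacement under the Zipf rank law; polarity i.i.d. per section rate.
    Planted associations then override the emission of their keyword for
    every case.  Deterministic given the config (single seeded stream).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    width = max(4, len(str(n)))
    case_ids = np.array([f"c{i:0{width}d}" for i in range(1, n + 1)])

    codes = list(config.diagnosis_probs)
    probs = np.array([config.diagnosis_probs[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    dx = np.array(codes, dtype=object)[rng.choice(len(codes), size=n, p=probs)]

    frames = []
    for section, m, mean, p_pos in (
        ("Hx", config.n_keywords_hx, config.mean_ak_per_case_hx, config.p_positive_given_hx),
        ("Px", config.n_keywords_px, config.mean_ak_per_case_px, config.p_positive_given_px),
    ):
        names = np.array(config.keyword_names(section), dtype=object)
        case_idx, kw_idx = _sample_section(rng, n, m, mean, config.zipf_exponent)
        pol = np.where(rng.random(len(kw_idx)) < p_pos, "pos", "neg")
        frames.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[case_idx],
                    "keyword": names[kw_idx],
                    "section": section,
                    "polarity": pol,
                }
            )
        )
    ann = pd.concat(frames, ignore_index=True)

    # planted associations: last one naming a keyword wins
    by_keyword: dict[str, PlantedAssociation] = {}
    for assoc in config.planted:
        by_keyword[assoc.keyword] = assoc
    sections = dict(
        zip(config.inventory()["keyword"], config.inventory()["section"])
    )
    for kw, assoc in by_keyword.items():
        ann = ann[ann["keyword"] != kw]
        has_dx = dx == assoc.diagnosis
        u = rng.random(n)
        pol = np.where(
            has_dx,
            np.where(u < assoc.sensitivity, "pos", "neg"),
            np.where(u < assoc.specificity, "neg", "pos"),
        )
        frames = pd.DataFrame(
            {
                "case_id": case_ids,
                "keyword": kw,
                "section": sections[kw],
                "polarity": pol,
            }
        )
        ann = pd.concat([ann, frames], ignore_index=True)

    order_key = ann["case_id"].map({c: i for i, c in enumerate(case_ids)})
    ann = (
        ann.assign(_k=order_key)
        .sort_values(["_k", "section", "keyword"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    cases = pd.DataFrame({"case_id": case_ids, "diagnosis": dx})
    return Corpus(cases, ann)
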