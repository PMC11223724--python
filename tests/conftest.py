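import numpy as np
import pandas as pd
import pytest

from keywordlr import Corpus, default_config, generate_corpus


@pytest.fixture
def toy_corpus() -> Corpus:
    """Three cases, two diagnoses, three keywords (hand-checkable)."""
    frame = pd.DataFrame(
        [
            ("c1", "A", "nausea", "Hx", "pos"),
            ("c1", "A", "fever", "Hx", "neg"),
            ("c1", "A", "pharyngeal erythema", "Px", "pos"),
            ("c2", "B", "nausea", "Hx", "neg"),
            ("c2", "B", "fever", "Hx", "pos"),
            ("c3", "A", "fever", "Hx", "neg"),
        ],
        columns=["case_id", "diagnosis", "keyword", "section", "polarity"],
    )
    return Corpus.from_frame(frame)


@pytest.fixture(scope="session")
def default_corpus() -> Corpus:
    """One draw of the default 270-case synthetic corpus."""
    return generate_corpus(default_config(seed=1))


def random_corpus_frame(rng: np.random.Generator, n_cases=12, n_kw=15) -> pd.DataFrame:
    """Small random but valid corpus as a long frame (for property tests)."""
    sections = {f"k{i}": ("Hx" if i % 3 else "Px") for i in range(n_kw)}
    rows = []
    for c in range(n_cases):
        dx = f"D{rng.integers(0, 4)}"
        kws = rng.choice(n_kw, size=rng.integers(1, min(6, n_kw) + 1), replace=False)
        for k in kws:
            kw = f"k{k}"
            pol = "pos" if rng.random() < 0.5 else "neg"
            rows.append((f"c{c}", dx, kw, sections[kw], pol))
    return pd.DataFrame(
        rows, columns=["case_id", "diagnosis", "keyword", "section", "polarity"]
    )
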