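"""Contingency counting rule, operational characteristics, CIs, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from keywordlr import (
    ContingencyCounts,
    Corpus,
    PlantedAssociation,
    SynthConfig,
    build_cross_table,
    chi_squared_2x2,
    contingency,
    calculability_summary,
    operational_characteristics,
    plant_association,
    proportion_ci,
    generate_corpus,
    significant_combinations,
)
from keywordlr.crosstable import DegenerateTableError, LookupError_
from tests.conftest import random_corpus_frame


def corpus_from(rows):
    return Corpus.from_frame(
        pd.DataFrame(
            rows, columns=["case_id", "diagnosis", "keyword", "section", "polarity"]
        )
    )


class TestContingency:
    """Hand application of the TP/TN counting-and-subtraction rule."""

    @pytest.fixture
    def three_cases(self):
        # (dx A, K pos), (dx B, K neg), (dx A, K null)
        return corpus_from(
            [
                ("c1", "A", "K", "Hx", "pos"),
                ("c2", "B", "K", "Hx", "neg"),
                ("c3", "A", "other", "Hx", "pos"),
            ]
        )

    def test_rule_for_diagnosis_with_positive(self, three_cases):
        cc = contingency(three_cases, "A", "K")
        assert cc.as_tuple() == (1, 0, 0, 1)

    def test_rule_for_other_diagnosis(self, three_cases):
        cc = contingency(three_cases, "B", "K")
        assert cc.as_tuple() == (0, 1, 1, 0)

    def test_null_keyword_contributes_nothing(self, three_cases):
        assert contingency(three_cases, "A", "other").as_tuple() == (1, 0, 0, 0)

    def test_unknown_lookups_raise(self, three_cases):
        with pytest.raises(LookupError_):
            contingency(three_cases, "Z", "K")
        with pytest.raises(LookupError_):
            contingency(three_cases, "A", "missing")


class TestCrossTable:
    def test_cell_count_is_product(self, toy_corpus):
        table = build_cross_table(toy_corpus)
        assert table.n_cells == len(table.diagnoses) * len(table.keywords) == 6

    def test_cells_match_direct_contingency(self, toy_corpus):
        table = build_cross_table(toy_corpus)
        for d, k, cell in table.cells():
            assert cell == contingency(toy_corpus, d, k)

    def test_single_cell_table(self):
        corpus = corpus_from([("c1", "A", "K", "Hx", "pos")])
        table = build_cross_table(corpus)
        assert table.n_cells == 1
        assert table["A", "K"].as_tuple() == (1, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_corpora(self, seed):
        """tp+fp and fn+tn reproduce each keyword's polarity totals."""
        rng = np.random.default_rng(seed)
        corpus = Corpus.from_frame(random_corpus_frame(rng, n_cases=20, n_kw=10))
        table = build_cross_table(corpus)
        ann = corpus.annotations
        for _, k, cell in table.cells():
            n_pos = int(((ann["keyword"] == k) & (ann["polarity"] == "pos")).sum())
            n_neg = int(((ann["keyword"] == k) & (ann["polarity"] == "neg")).sum())
            assert cell.tp + cell.fp == n_pos
            assert cell.fn + cell.tn == n_neg

    def test_two_diagnosis_complementarity(self):
        rng = np.random.default_rng(11)
        frame = random_corpus_frame(rng, n_cases=20, n_kw=8)
        frame["diagnosis"] = frame["case_id"].map(
            lambda c: "A" if int(c[1:]) % 2 else "B"
        )
        corpus = Corpus.from_frame(frame)
        table = build_cross_table(corpus)
        for k in table.keywords:
            a, b = table["A", k], table["B", k]
            assert a.tp + b.tp == a.tp + a.fp  # B's true positives are A's false ones
            assert a.tp == b.fp and a.fn == b.tn and a.tn == b.fn and a.fp == b.tp


class TestProportionCI:
    def test_clopper_pearson_zero_successes(self):
        lo, hi = proportion_ci(0, 10, "clopper_pearson")
        assert lo == 0.0
        assert 0 < hi < 1

    @pytest.mark.parametrize(
        "k,n,expected",
        [(1, 2, (0.095, 0.905)), (2, 4, (0.150, 0.850))],
    )
    def test_wilson_closed_form(self, k, n, expected):
        lo, hi = proportion_ci(k, n, "wilson")
        assert (round(lo, 3), round(hi, 3)) == expected

    @pytest.mark.parametrize("k,n", [(1, 2), (3, 10), (0, 7), (25, 50)])
    def test_wilson_matches_score_inversion_oracle(self, k, n):
        """Wilson bounds solve |p_hat - p| = z sqrt(p(1-p)/n) (bisection)."""
        z = stats.norm.ppf(0.975)
        p_hat = k / n

        def score(p):
            return (p_hat - p) ** 2 - z**2 * p * (1 - p) / n

        lo, hi = proportion_ci(k, n, "wilson")
        for bound in (lo, hi):
            assert abs(score(bound)) < 1e-10

    def test_clopper_pearson_matches_binomtest(self):
        for k, n in [(1, 2), (3, 10), (9, 12)]:
            res = stats.binomtest(k, n).proportion_ci(0.95, method="exact")
            lo, hi = proportion_ci(k, n, "clopper_pearson")
            assert lo == pytest.approx(res.low, abs=1e-12)
            assert hi == pytest.approx(res.high, abs=1e-12)

    def test_interval_brackets_point_estimate(self):
        for method in ("wilson", "clopper_pearson"):
            lo, hi = proportion_ci(7, 20, method)
            assert 0 <= lo <= 7 / 20 <= hi <= 1

    def test_n_zero_is_undefined(self):
        with pytest.raises(DegenerateTableError):
            proportion_ci(0, 0)


class TestOperationalCharacteristics:
    def test_strong_examination_finding(self):
        # sparse cell reminiscent of a rare but near-pathognomonic sign
        oc = operational_characteristics(ContingencyCounts(1, 1, 1, 125))
        assert oc.sensitivity == 0.5
        assert oc.specificity == pytest.approx(125 / 126)
        assert oc.plr == pytest.approx(63.0)
        assert all(oc.calculable.values())

    def test_zero_cells_flag_lr_incalculable(self):
        oc = operational_characteristics(ContingencyCounts(5, 0, 0, 5))
        assert oc.ppv == 1.0 and oc.sensitivity == 1.0
        assert oc.calculable["ppv"] and oc.calculable["sensitivity"]
        assert not oc.calculable["plr"] and oc.plr is None

    def test_symmetric_cell(self):
        oc = operational_characteristics(ContingencyCounts(1, 1, 1, 1))
        assert oc.sensitivity == oc.specificity == 0.5
        assert oc.plr == pytest.approx(1.0) and oc.nlr == pytest.approx(1.0)

    def test_all_metrics_absent_on_empty_cell(self):
        oc = operational_characteristics(ContingencyCounts(0, 0, 0, 0))
        assert not any(oc.calculable.values())
        assert oc.sensitivity is None and oc.plr is None

    @pytest.mark.parametrize("seed", range(20))
    def test_lr_identity(self, seed):
        """plr (1 - specificity) = sensitivity wherever both are defined."""
        rng = np.random.default_rng(seed)
        cc = ContingencyCounts(*(int(v) for v in rng.integers(1, 40, 4)))
        oc = operational_characteristics(cc)
        assert oc.plr * (1 - oc.specificity) == pytest.approx(
            oc.sensitivity, abs=1e-12
        )
        assert oc.nlr * oc.specificity == pytest.approx(
            1 - oc.sensitivity, abs=1e-12
        )

    def test_lr_ci_uses_log_transform(self):
        cc = ContingencyCounts(10, 5, 4, 40)
        oc = operational_characteristics(cc, alpha=0.05)
        se = np.sqrt(1 / 10 - 1 / 14 + 1 / 5 - 1 / 45)
        z = stats.norm.ppf(0.975)
        lo, hi = oc.ci["plr"]
        assert lo == pytest.approx(oc.plr * np.exp(-z * se))
        assert hi == pytest.approx(oc.plr * np.exp(z * se))


class TestChiSquared:
    def test_no_association_is_zero(self):
        stat, p = chi_squared_2x2(ContingencyCounts(5, 5, 5, 5))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_perfect_association_hand_formula(self):
        stat, _ = chi_squared_2x2(ContingencyCounts(10, 0, 0, 10))
        assert stat == pytest.approx(20.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_correction_never_increases_statistic(self, seed):
        rng = np.random.default_rng(seed)
        cc = ContingencyCounts(*(int(v) for v in rng.integers(1, 30, 4)))
        plain, _ = chi_squared_2x2(cc, correction=False)
        corrected, _ = chi_squared_2x2(cc, correction=True)
        assert plain >= corrected - 1e-12

    def test_all_zero_table_is_error(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_2x2(ContingencyCounts(0, 0, 0, 0))


class TestCalculability:
    def test_toy_enumeration(self):
        # 2 diagnoses x 2 keywords; exactly one keyword has all cells >= 1
        corpus = corpus_from(
            [
                ("c1", "A", "K", "Hx", "pos"),
                ("c2", "A", "K", "Hx", "neg"),
                ("c3", "B", "K", "Hx", "pos"),
                ("c4", "B", "K", "Hx", "neg"),
                ("c5", "A", "J", "Px", "pos"),
            ]
        )
        rep = calculability_summary(build_cross_table(corpus))
        assert rep.totals["total"] == 4
        assert rep.counts.loc["lr", "total"] == 2  # (A,K) and (B,K)
        assert rep.percents.loc["lr", "total"] == 50.0
        assert rep.counts.loc["lr", "Px"] == 0
        # J's single positive annotation makes tp+fp = 1 in both Px cells
        assert rep.counts.loc["ppv", "Px"] == 2

    def test_report_matches_per_cell_flags(self, default_corpus):
        table = build_cross_table(default_corpus)
        rep = calculability_summary(table)
        recount = 0
        for d, k, cell in table.cells():
            oc = operational_characteristics(cell)
            recount += oc.calculable["plr"]
        assert rep.counts.loc["lr", "total"] == recount
        assert rep.totals["total"] == table.n_cells
        # section strata partition the total
        assert (
            rep.counts.loc["lr", "Hx"] + rep.counts.loc["lr", "Px"]
            == rep.counts.loc["lr", "total"]
        )


class TestSignificantCombinations:
    def test_planted_strong_association_is_found(self):
        cfg = SynthConfig(
            n_cases=600,
            diagnosis_probs={"A": 0.4, "B": 0.6},
            n_keywords_hx=20,
            n_keywords_px=8,
            zipf_exponent=1.0,
            mean_ak_per_case_hx=5.0,
            mean_ak_per_case_px=2.0,
            p_positive_given_hx=0.6,
            p_positive_given_px=0.2,
            seed=9,
        )
        cfg = plant_association(cfg, PlantedAssociation("A", "hx001", 0.85, 0.85))
        table = build_cross_table(generate_corpus(cfg))
        hits = significant_combinations(table, alpha=0.05)
        assert ("A", "hx001") in {(h.diagnosis, h.keyword) for h in hits}

    def test_alpha_zero_empty(self, default_corpus):
        table = build_cross_table(default_corpus)
        assert significant_combinations(table, alpha=1e-300) == []

    def test_rows_sorted_and_complete(self, default_corpus):
        table = build_cross_table(default_corpus)
        hits = significant_combinations(table, alpha=0.05)
        keys = [(h.section, h.keyword, h.diagnosis) for h in hits]
        assert keys == sorted(keys)
        for h in hits:
            assert all(h.opchar.calculable.values())
            assert h.opchar.p_value < 0.05

    def test_bonferroni_is_stricter(self, default_corpus):
        table = build_cross_table(default_corpus)
        raw = significant_combinations(table, alpha=0.05)
        adj = significant_combinations(table, alpha=0.05, multiplicity="bonferroni")
        assert len(adj) <= len(raw)
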