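"""Kano engine: pair classification, tallies, categories, coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kanopr.kano import (
    ANSWER_LEVELS,
    DEFAULT_TIE_BREAK,
    EVALUATION_TABLE,
    AnswerLevel,
    CategoryCounts,
    KanoAnalyzer,
    KanoCategory,
    assign_final_category,
    assign_quadrant,
    classify_response_pair,
    results_from_counts,
    run_kano,
    satisfaction_coefficients,
    tally_categories,
)
from kanopr.reference import REFERENCE_FINAL_CATEGORIES
from kanopr.registry import ATTRIBUTES, DIMENSIONS, get_attribute

# Independent transcription of the 5x5 evaluation grid, cell by cell
# (functional level, dysfunctional level) -> category.
ORACLE_GRID = {
    ("Like it", "Like it"): "Q",
    ("Like it", "Must-be"): "A",
    ("Like it", "Neutral"): "A",
    ("Like it", "Accept it"): "A",
    ("Like it", "Dislike"): "O",
    ("Must-be", "Like it"): "R",
    ("Must-be", "Must-be"): "I",
    ("Must-be", "Neutral"): "I",
    ("Must-be", "Accept it"): "I",
    ("Must-be", "Dislike"): "M",
    ("Neutral", "Like it"): "R",
    ("Neutral", "Must-be"): "I",
    ("Neutral", "Neutral"): "I",
    ("Neutral", "Accept it"): "I",
    ("Neutral", "Dislike"): "M",
    ("Accept it", "Like it"): "R",
    ("Accept it", "Must-be"): "I",
    ("Accept it", "Neutral"): "I",
    ("Accept it", "Accept it"): "I",
    ("Accept it", "Dislike"): "M",
    ("Dislike", "Like it"): "R",
    ("Dislike", "Must-be"): "R",
    ("Dislike", "Neutral"): "R",
    ("Dislike", "Accept it"): "R",
    ("Dislike", "Dislike"): "Q",
}


class TestClassification:
    def test_all_25_pairs_match_grid_oracle(self):
        assert len(EVALUATION_TABLE) == 25
        for (f, d), expected in ORACLE_GRID.items():
            assert classify_response_pair(f, d).value == expected

    @pytest.mark.parametrize(
        "functional,dysfunctional,expected",
        [
            ("Like it", "Dislike", "O"),
            ("Like it", "Like it", "Q"),
            ("Must-be", "Dislike", "M"),
            ("Accept it", "Like it", "R"),
            ("Neutral", "Neutral", "I"),
        ],
    )
    def test_landmark_cells(self, functional, dysfunctional, expected):
        assert classify_response_pair(functional, dysfunctional).value == expected

    def test_non_canonical_level_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            classify_response_pair("Love it", "Dislike")
        with pytest.raises(ValueError, match="dysfunctional"):
            classify_response_pair("Like it", "meh")


class TestRegistry:
    def test_attributes_contiguous_and_unique(self):
        assert sorted(ATTRIBUTES) == list(range(1, 19))

    def test_dimension_sizes(self):
        sizes = [sum(a.dimension == d for a in ATTRIBUTES.values()) for d in DIMENSIONS]
        assert sizes == [3, 3, 2, 2, 3, 2, 1, 2]

    def test_unknown_attribute_fails_loudly(self):
        with pytest.raises(KeyError, match="unknown attribute id"):
            get_attribute(19)


class TestTally:
    def test_reproduces_published_row(self, reference_pairs):
        counts = tally_categories(reference_pairs[7])
        assert (counts.a, counts.o, counts.m, counts.i, counts.r, counts.q) == (
            4, 204, 6, 23, 0, 0,
        )

    def test_empty_input_gives_zero_tally(self):
        counts = tally_categories([])
        assert counts.n_total == 0

    def test_permutation_invariance_and_missing_halves(self, reference_pairs):
        pairs = list(reference_pairs[2])
        base = tally_categories(pairs)
        assert tally_categories(pairs[::-1]) == base
        with_missing = pairs + [("Like it", None), (None, "Dislike"), (None, None)]
        assert tally_categories(with_missing) == base
        assert base.n_total == len(pairs)

    def test_percentages_sum_to_100(self, table3_counts):
        for counts in table3_counts.values():
            assert counts.percentages().sum() == pytest.approx(100.0)


class TestFinalCategory:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (CategoryCounts(31, 143, 2, 60, 1, 0), "O"),
            (CategoryCounts(6, 56, 1, 173, 1, 0), "I"),
            (CategoryCounts(0, 50, 50, 0, 0, 0), "M"),  # tie broken toward must-be
        ],
    )
    def test_modal_assignment(self, counts, expected):
        assert assign_final_category(counts).value == expected

    def test_tie_break_priority_total_order(self):
        # equal counts everywhere: the fixed priority decides outright
        counts = CategoryCounts(5, 5, 5, 5, 5, 5)
        assert assign_final_category(counts) is KanoCategory.MUST_BE
        assert [c.value for c in DEFAULT_TIE_BREAK] == ["M", "O", "A", "I", "R", "Q"]

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            assign_final_category(CategoryCounts())


class TestCoefficients:
    @pytest.mark.parametrize(
        "counts,si,dsi",
        [
            # direct evaluation of the formulas on published tallies
            (CategoryCounts(4, 204, 6, 23), 208 / 237, -210 / 237),
            (CategoryCounts(31, 143, 2, 60), 174 / 236, -145 / 236),
            (CategoryCounts(0, 0, 5, 5), 0.0, -0.5),
        ],
    )
    def test_formula(self, counts, si, dsi):
        pair = satisfaction_coefficients(counts)
        assert pair.si == pytest.approx(si)
        assert pair.dsi == pytest.approx(dsi)

    def test_reverse_questionable_excluded_from_denominator(self):
        with_rq = satisfaction_coefficients(CategoryCounts(4, 204, 6, 23, 100, 50))
        without = satisfaction_coefficients(CategoryCounts(4, 204, 6, 23))
        assert with_rq == without

    def test_undefined_when_no_classifiable_answers(self):
        pair = satisfaction_coefficients(CategoryCounts(r=3, q=2))
        assert not pair.defined and math.isnan(pair.si)
        with pytest.raises(ValueError):
            assign_quadrant(pair)

    @given(
        a=st.integers(0, 200), o=st.integers(0, 200),
        m=st.integers(0, 200), i=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_identity(self, a, o, m, i):
        if a + o + m + i == 0:
            return
        pair = satisfaction_coefficients(CategoryCounts(a, o, m, i))
        assert 0.0 <= pair.si <= 1.0
        assert -1.0 <= pair.dsi <= 0.0
        # si - |dsi| = (A - M) / (A+O+M+I) identically
        assert pair.si - abs(pair.dsi) == pytest.approx((a - m) / (a + o + m + i))

    def test_monotonicity_moving_indifferent_to_one_dimensional(self):
        before = satisfaction_coefficients(CategoryCounts(10, 50, 10, 30))
        after = satisfaction_coefficients(CategoryCounts(10, 51, 10, 29))
        assert after.si > before.si
        assert abs(after.dsi) > abs(before.dsi)


class TestQuadrant:
    @pytest.mark.parametrize(
        "si,dsi,expected",
        [
            (208 / 237, -210 / 237, 1),  # both high
            (131 / 237, -102 / 237, 2),  # high SI only
            (0.2, -0.1, 3),
            (0.3, -0.8, 4),
            (0.5, -0.5, 3),  # boundary: split itself is not "above"
        ],
    )
    def test_split_half(self, si, dsi, expected):
        from kanopr.kano import CoefficientPair

        assert assign_quadrant(CoefficientPair(si, dsi), 0.5) == expected

    def test_per_axis_split(self):
        from kanopr.kano import CoefficientPair

        assert assign_quadrant(CoefficientPair(0.6, -0.3), (0.5, 0.25)) == 1


class TestRunKano:
    def test_reference_frame_reproduces_all_final_categories(self, reference_frame):
        results = run_kano(reference_frame)
        for res in results:
            assert res.final_category == REFERENCE_FINAL_CATEGORIES[res.attribute.id]
        finals = [r.final_category.value for r in results]
        assert finals.count("O") == 9 and finals.count("I") == 9

    def test_uniform_enthusiast_cohort(self):
        import pandas as pd

        row = {}
        for aid in ATTRIBUTES:
            row[f"F{aid:02d}"] = "Like it"
            row[f"D{aid:02d}"] = "Dislike"
        results = run_kano(pd.DataFrame([row]))
        for res in results:
            assert res.final_category is KanoCategory.ONE_DIMENSIONAL
            assert res.coefficients.si == 1.0
            assert res.coefficients.dsi == -1.0
            assert res.quadrant == 1

    def test_large_calibrated_cohort_matches_published_modes(self):
        from kanopr import respondents_to_frame, simulate_cohort

        frame = respondents_to_frame(simulate_cohort(n_respondents=5000, seed=7))
        results = run_kano(frame)
        for res in results:
            assert res.final_category == REFERENCE_FINAL_CATEGORIES[res.attribute.id]

    def test_analyzer_estimator_api(self, reference_frame):
        analyzer = KanoAnalyzer(split=0.5)
        assert analyzer.get_params()["split"] == 0.5
        analyzer.set_params(split=0.4).fit(reference_frame)
        assert len(analyzer.results_) == 18
        summary = analyzer.transform()
        assert list(summary.index) == list(range(1, 19))
        with pytest.raises(AttributeError):
            KanoAnalyzer().transform()

    def test_mean_split_analyzer(self, reference_frame):
        analyzer = KanoAnalyzer(split="mean").fit(reference_frame)
        si_split, dsi_split = analyzer.split_
        sis = [r.coefficients.si for r in analyzer.results_]
        assert si_split == pytest.approx(np.mean(sis))

    def test_results_from_counts_flags_modal_reverse(self):
        results = results_from_counts({1: CategoryCounts(1, 1, 1, 1, 10, 0)})
        assert results[0].final_category is KanoCategory.REVERSE
        assert results[0].flagged and results[0].quadrant is None
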