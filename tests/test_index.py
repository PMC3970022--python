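"""The index formulas: MTAi, asymmetry, and longitudinal yearly rates."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtai import (
    DomainError,
    RegionAreas,
    ValidationError,
    classify_asymmetry,
    compute_ia,
    compute_mtai,
    compute_yrmta,
    compute_yrmtar,
    months_between,
    reference_table,
    summarize_bilateral,
    summarize_longitudinal,
)
from mtai.index import REFERENCE_TABLE_DISCLAIMER


def areas(A, B, C, hemisphere="LEFT", date=None):
    return RegionAreas(hemisphere, A=A, B=B, C=C, study_date=date)


class TestComputeMtai:
    @pytest.mark.parametrize(
        "A, B, C, expected_2dp",
        [
            (326.5, 201.4, 189.7, 6.59),  # worked example, right hemisphere
            (326.5, 224.0, 175.2, 5.85),  # worked example, left hemisphere
            (110.0, 100.0, 100.0, 1.0),
        ],
    )
    def test_worked_examples(self, A, B, C, expected_2dp):
        assert round(compute_mtai(areas(A, B, C)), 2) == expected_2dp

    def test_zero_atrophy_gives_zero_index(self):
        assert compute_mtai(areas(200.0, 200.0, 57.0)) == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.floats(1, 1e4),
        b_frac=st.floats(0.01, 1),
        c=st.floats(1, 1e4),
        s=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, a, b_frac, c, s):
        b = a * b_frac
        base = compute_mtai(areas(a, b, c))
        scaled = compute_mtai(areas(a * s, b * s, c * s))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_monotone_in_parenchyma_and_ventricle(self):
        A, C = 330.0, 165.0
        by_b = [compute_mtai(areas(A, b, C)) for b in (300, 250, 200, 150)]
        assert all(x < y for x, y in zip(by_b, by_b[1:]))
        by_c = [compute_mtai(areas(A, 290.0, c)) for c in (100, 150, 200, 250)]
        assert all(x > y for x, y in zip(by_c, by_c[1:]))


class TestIndexOfAsymmetry:
    def test_formula_on_worked_example_values(self):
        # 2-decimal hemispheric indices in, percent out
        assert round(compute_ia(5.85, 6.59), 2) == -5.95

    @pytest.mark.parametrize("l, r, expected", [(4.0, 4.0, 0.0), (2.0, 1.0, 33.33)])
    def test_simple_cases(self, l, r, expected):
        assert round(compute_ia(l, r), 2) == expected

    def test_both_zero_is_undefined(self):
        with pytest.raises(DomainError):
            compute_ia(0.0, 0.0)

    def test_negative_index_rejected(self):
        with pytest.raises(DomainError):
            compute_ia(-1.0, 2.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(l=st.floats(0, 100), r=st.floats(0, 100))
    def test_antisymmetry_and_bounds(self, l, r):
        if l + r == 0:
            return
        ia = compute_ia(l, r)
        assert compute_ia(r, l) == pytest.approx(-ia, abs=1e-12)
        assert -100.0 <= ia <= 100.0
        assert (ia < 0) == (r > l)


class TestClassifyAsymmetry:
    @pytest.mark.parametrize(
        "ia, expected",
        [(0.0, False), (2.9, False), (-5.95, True), (3.0, True), (-3.0, True)],
    )
    def test_default_threshold(self, ia, expected):
        assert classify_asymmetry(ia) is expected

    def test_configurable_threshold(self):
        assert classify_asymmetry(4.0, threshold=5.0) is False
        assert classify_asymmetry(4.0, threshold=4.0) is True


class TestSummarizeBilateral:
    def test_worked_example(self, worked_example_left, worked_example_right):
        res = summarize_bilateral(worked_example_left, worked_example_right)
        assert round(res.left_mtai, 2) == 5.85
        assert round(res.right_mtai, 2) == 6.59
        assert round(res.median_mtai, 2) == 6.22
        assert res.asymmetric is True
        assert res.ia_percent < 0  # right index exceeds left
        assert res.median_mtai == pytest.approx(
            (res.left_mtai + res.right_mtai) / 2
        )

    def test_symmetric_case(self):
        res = summarize_bilateral(
            areas(330, 290, 165, "LEFT"), areas(330, 290, 165, "RIGHT")
        )
        assert res.ia_percent == 0.0
        assert res.asymmetric is False
        assert res.median_mtai == pytest.approx(res.left_mtai)

    def test_one_sided_zero_index_gives_full_asymmetry(self):
        res = summarize_bilateral(
            areas(300, 300, 150, "LEFT"), areas(330, 290, 165, "RIGHT")
        )
        assert res.left_mtai == 0.0
        assert res.ia_percent == pytest.approx(-100.0)

    def test_hemisphere_tags_enforced(self):
        left = areas(330, 290, 165, "LEFT")
        with pytest.raises(ValidationError):
            summarize_bilateral(left, left)


class TestLongitudinalRates:
    def test_no_change_is_zero_rate(self):
        first = areas(330, 290, 165)
        second = areas(320, 280, 180)  # same A - B
        for months in (1, 12, 60):
            assert compute_yrmta(first, second, months) == 0.0

    @pytest.mark.parametrize(
        "loss1, loss2, months, expected",
        [
            ((300, 200), (310, 200), 12, 100.0),
            ((300, 200), (305, 200), 6, 100.0),
        ],
    )
    def test_annualized_area_change(self, loss1, loss2, months, expected):
        first = areas(loss1[0], loss1[1], 150.0)
        second = areas(loss2[0], loss2[1], 150.0)
        assert compute_yrmta(first, second, months) == pytest.approx(expected)

    def test_rate_scales_inversely_with_interval(self):
        first, second = areas(300, 200, 150), areas(320, 200, 150)
        r12 = compute_yrmta(first, second, 12)
        r24 = compute_yrmta(first, second, 24)
        assert r24 == pytest.approx(r12 / 2)

    def test_relative_rate_normalizes_by_ventricular_change(self):
        first = areas(300, 200, 150)
        second = areas(310, 200, 160)  # numerator 10, dC 10
        # 10 x 120 / (10 x 12)
        assert compute_yrmtar(first, second, 12) == pytest.approx(10.0)

    def test_relative_rate_zero_numerator(self):
        first, second = areas(300, 200, 150), areas(300, 200, 170)
        assert compute_yrmtar(first, second, 18) == 0.0

    def test_relative_rate_undefined_without_ventricular_change(self):
        first, second = areas(300, 200, 150), areas(310, 200, 150)
        with pytest.raises(DomainError):
            compute_yrmtar(first, second, 12)

    def test_invalid_interval_and_hemisphere_mismatch(self):
        first, second = areas(300, 200, 150), areas(310, 200, 160)
        with pytest.raises(DomainError):
            compute_yrmta(first, second, 0)
        with pytest.raises(ValidationError):
            compute_yrmta(first, areas(310, 200, 160, "RIGHT"), 12)

    def test_summarize_uses_study_dates(self):
        d1, d2 = datetime.date(2014, 1, 1), datetime.date(2015, 1, 1)
        first = areas(300, 200, 150, date=d1)
        second = areas(310, 200, 160, date=d2)
        res = summarize_longitudinal(first, second)
        months = months_between(d1, d2)
        assert months == pytest.approx(12.0, rel=1e-2)
        assert res.yr_mta == pytest.approx(10 * 120 / months)
        assert res.yr_mta_relative == pytest.approx(10 * 120 / (10 * months))

    def test_summarize_relative_is_none_when_undefined(self):
        first = areas(300, 200, 150)
        second = areas(310, 200, 150)
        res = summarize_longitudinal(first, second, months=12)
        assert res.yr_mta_relative is None


class TestReferenceTable:
    def test_seven_illustrative_groups(self):
        rows = reference_table()
        assert len(rows) == 7
        by_group = {r.group: r for r in rows}
        assert by_group["HealthyControl"].mean_mmtai == 2.4
        assert by_group["HealthyControl"].mean_ia == 1.8
        assert by_group["MildAD"].mean_mmtai == 4.6
        assert by_group["FTLD"].mean_ia == 8.2

    def test_disclaimer_marks_table_non_normative(self):
        assert "not informative" in REFERENCE_TABLE_DISCLAIMER
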