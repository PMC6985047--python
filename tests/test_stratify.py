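import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agemix.errors import AgemixWarning, DegenerateDataError, TieWarning
from agemix.io import CaseRecord
from agemix.stratify import (
    ER_CATEGORIES,
    assign_clinical_er,
    assign_er_category,
    assign_quartiles,
    assign_tumor_characteristic_strata,
    filter_pam50,
    normalize_pam50_label,
    standardize_esr1,
)


class TestErCategory:
    @pytest.mark.parametrize(
        "value,category",
        [
            (0.0, "negative"),
            (0.5, "negative"),
            (1.0, "borderline"),
            (9.99, "borderline"),
            (10.0, "low"),
            (39.9, "low"),
            (40.0, "intermediate"),
            (79.9, "intermediate"),
            (80.0, "high"),
            (100.0, "high"),
        ],
    )
    def test_partition(self, value, category):
        assert assign_er_category(value).category == category

    def test_very_high_nests_in_high(self):
        a = assign_er_category(96.0)
        assert a.category == "high" and a.very_high
        assert not assign_er_category(94.9).very_high

    @given(st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_category(self, er):
        a = assign_er_category(er)
        assert a.category in ER_CATEGORIES
        if a.very_high:
            assert a.category == "high"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_er_category(101.0)
        with pytest.raises(ValueError):
            assign_er_category(-0.1)


class TestClinicalEr:
    @pytest.mark.parametrize(
        "er,cut,status",
        [
            (5.0, 1, "positive"),
            (5.0, 10, "negative"),
            (10.0, 10, "positive"),  # boundary closed
            (1.0, 1, "positive"),
            (0.5, 1, "negative"),
        ],
    )
    def test_cutpoints(self, er, cut, status):
        assert assign_clinical_er(er, cut) == status

    def test_other_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            assign_clinical_er(50.0, 5)


class TestStandardize:
    def test_small_example(self):
        out = standardize_esr1([1.0, 2.0, 3.0])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_order_preserved(self):
        x = np.array([3.0, -1.0, 7.0, 2.0])
        out = standardize_esr1(x)
        assert list(np.argsort(out)) == list(np.argsort(x))

    def test_large_sample(self):
        x = np.random.default_rng(4).normal(5, 2, 10_000)
        out = standardize_esr1(x)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_zero_spread(self):
        with pytest.raises(DegenerateDataError):
            standardize_esr1([2.0, 2.0, 2.0])


class TestQuartiles:
    def test_remainder_goes_to_top(self):
        # n = 1965 -> Q4 has 492, Q1..Q3 have 491
        x = np.random.default_rng(1).permutation(1965).astype(float)
        labels = assign_quartiles(x)
        counts = {q: int((labels == q).sum()) for q in ("Q1", "Q2", "Q3", "Q4")}
        assert counts == {"Q1": 491, "Q2": 491, "Q3": 491, "Q4": 492}

    def test_eight_values_two_each(self):
        labels = assign_quartiles([5.0, 1.0, 7.0, 3.0, 8.0, 2.0, 6.0, 4.0])
        assert sorted(labels) == ["Q1"] * 2 + ["Q2"] * 2 + ["Q3"] * 2 + ["Q4"] * 2

    def test_labels_monotone_in_value(self):
        x = np.random.default_rng(2).normal(size=101)
        labels = assign_quartiles(x)
        ranked = sorted(zip(x, labels))
        seq = [int(l[1]) for _, l in ranked]
        assert seq == sorted(seq)

    def test_all_equal_warns_stable_order(self):
        with pytest.warns(TieWarning):
            labels = assign_quartiles([1.0] * 8)
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    @given(st.integers(4, 200))
    @settings(max_examples=30, deadline=None)
    def test_sizes_differ_by_at_most_one(self, n):
        labels = assign_quartiles(np.arange(n, dtype=float))
        counts = [int((labels == f"Q{q}").sum()) for q in (1, 2, 3, 4)]
        assert max(counts) - min(counts) <= 1
        assert sum(counts) == n


def _rec(i, pam50):
    return CaseRecord(case_id=str(i), age=50.0, pam50=pam50)


class TestFilterPam50:
    def test_drops_normal_like(self):
        recs = [_rec(i, s) for i, s in enumerate(
            ["LumA", "LumB", "Her2", "Basal", "Normal"]
        )]
        with pytest.warns(AgemixWarning):
            kept = filter_pam50(recs)
        assert [r.pam50 for r in kept] == ["LumA", "LumB", "Her2", "Basal"]

    def test_all_normal_warns_empty(self):
        with pytest.warns(AgemixWarning):
            kept = filter_pam50([_rec(i, "Normal") for i in range(3)])
        assert kept == []

    def test_aliases_normalized(self):
        recs = [_rec(0, "Luminal A"), _rec(1, "basal-like"), _rec(2, "HER2")]
        kept = filter_pam50(recs)
        assert [r.pam50 for r in kept] == ["LumA", "Basal", "Her2"]

    def test_idempotent(self):
        recs = [_rec(i, s) for i, s in enumerate(
            ["LumA", "Normal", "LumB", None]
        )]
        with pytest.warns(AgemixWarning):
            once = filter_pam50(recs)
        twice = filter_pam50(once)
        assert twice == once

    def test_label_aliases(self):
        assert normalize_pam50_label("Luminal B") == "LumB"
        assert normalize_pam50_label("normal-like") == "Normal"
        assert normalize_pam50_label("garbage") is None


class TestTumorCharacteristics:
    def test_size_cut(self):
        recs = [
            CaseRecord("a", 50.0, tumor_size=1.5),
            CaseRecord("b", 50.0, tumor_size=2.5),
        ]
        assert assign_tumor_characteristic_strata(recs, "size") == [
            "small",
            "large",
        ]

    def test_grade(self):
        recs = [CaseRecord("a", 50.0, grade=2)]
        assert assign_tumor_characteristic_strata(recs, "grade") == ["grade2"]

    def test_nodes(self):
        recs = [
            CaseRecord("a", 50.0, node_status="negative"),
            CaseRecord("b", 50.0, node_status="1"),
            CaseRecord("c", 50.0, node_status="3"),
        ]
        assert assign_tumor_characteristic_strata(recs, "nodes") == [
            "negative",
            "1",
            "2+",
        ]

    def test_unknown_values_excluded_with_warning(self):
        recs = [CaseRecord("a", 50.0, grade=None)]
        with pytest.warns(AgemixWarning):
            out = assign_tumor_characteristic_strata(recs, "grade")
        assert out == [None]

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            assign_tumor_characteristic_strata([], "stage")
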