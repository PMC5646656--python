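"""Per-chromosome metrics, Levan classification and karyotype summaries."""

import math

import pytest
from hypothesis import given, strategies as st

from karyodist import (
    INFINITE,
    ChromosomeClass,
    ChromosomePair,
    Karyotype,
    arm_ratio,
    centromeric_index,
    classify,
    format_formula,
    fundamental_number,
    parse_formula,
    summarize_karyotype,
    summary_from_formula,
    type_proportions,
    validate_measurements,
    zone_assign,
)

M, SM, ST, T = ChromosomeClass.M, ChromosomeClass.SM, ChromosomeClass.ST, ChromosomeClass.T


class TestArmMetrics:
    @pytest.mark.parametrize("sa,la,expected", [
        (2.36, 2.36, 1.00),   # equal-armed metacentric
        (1.23, 2.46, 2.00),
        (1.85, 3.14, 1.6973),  # ratio of mean arms; the plate-mean AR prints 1.70
    ])
    def test_arm_ratio(self, sa, la, expected):
        assert arm_ratio(sa, la) == pytest.approx(expected, abs=1e-4)

    def test_telocentric_infinite(self):
        assert arm_ratio(0, 3.02) == INFINITE

    @pytest.mark.parametrize("sa,la,expected", [
        (2.43, 2.54, 48.89),
        (1.52, 4.53, 25.12),
        (3.3, 3.3, 50.00),
    ])
    def test_centromeric_index(self, sa, la, expected):
        assert centromeric_index(sa, la) == pytest.approx(expected, abs=0.005)

    def test_telocentric_ci_zero(self):
        assert centromeric_index(0, 1.5) == 0.0

    @pytest.mark.parametrize("sa,la", [(-1, 2), (2, -1), (1, 0), (3, 2)])
    def test_invalid_arms_rejected(self, sa, la):
        with pytest.raises(ValueError):
            arm_ratio(sa, la)
        with pytest.raises(ValueError):
            centromeric_index(sa, la)

    def test_error_names_pair(self):
        with pytest.raises(ValueError, match="pair 7"):
            arm_ratio(3.0, 2.0, pair=7)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_equal_arms(self, x):
        assert arm_ratio(x, x) == 1.0
        assert centromeric_index(x, x) == pytest.approx(50.0)

    @given(st.floats(min_value=0.01, max_value=100), st.floats(min_value=1.0, max_value=50))
    def test_ci_ar_duality(self, sa, ar):
        """CI = 100 / (1 + AR) whenever the short arm exists."""
        la = sa * ar
        assert centromeric_index(sa, la) == pytest.approx(
            100.0 / (1.0 + arm_ratio(sa, la)), abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize("ar,expected", [
        (1.00, M), (1.40, M), (1.69, M),
        (1.70, SM), (2.99, SM),          # boundary pair is submetacentric
        (3.0, ST), (4.03, ST), (6.99, ST),
        (7.0, T), (8.90, T), (INFINITE, T),
    ])
    def test_levan_intervals_lower_inclusive(self, ar, expected):
        assert classify(ar) is expected

    def test_rejects_ar_below_one(self):
        with pytest.raises(ValueError):
            classify(0.9)

    @given(st.floats(min_value=1.0, max_value=50), st.floats(min_value=0, max_value=10))
    def test_monotone_toward_asymmetry(self, ar, delta):
        """Increasing AR never moves the class back toward metacentric."""
        order = [M, SM, ST, T]
        assert order.index(classify(ar + delta)) >= order.index(classify(ar))

    @given(st.floats(min_value=0.01, max_value=50), st.floats(min_value=1.0, max_value=60))
    def test_zone_assign_matches_classify(self, sa, ar):
        assert zone_assign(sa, sa * ar) is classify(arm_ratio(sa, sa * ar))

    @pytest.mark.parametrize("sa,la,expected", [
        (2.43, 2.54, M), (0.32, 2.86, T), (1, 1, M), (0, 2.0, T),
    ])
    def test_zone_examples(self, sa, la, expected):
        assert zone_assign(sa, la) is expected

    def test_all_printed_types_reproduced(self, table2):
        """classify(printed AR) equals the printed class on all 90 pairs."""
        for kt in table2.values():
            for pair in kt.pairs:
                assert classify(pair.reported_ar) is pair.reported_type, (
                    kt.species, pair.pair_index)


class TestSummaries:
    EXPECTED = {
        "O. minor": ("42M+6SM+4ST+8T", 108),
        "A. fangsiao": ("32M+16SM+12T", 108),
        "C. chinensis": ("38M+6SM+8ST+8T", 104),
    }

    @pytest.mark.parametrize("species", sorted(EXPECTED))
    def test_measured_karyotypes(self, table2, species):
        s = summarize_karyotype(table2[species])
        formula, fn = self.EXPECTED[species]
        assert s.formula == formula
        assert s.fn == fn
        assert s.two_n == 60
        assert sum(s.counts.values()) == s.two_n
        assert all(v % 2 == 0 for v in s.counts.values())

    def test_trivial_single_class(self):
        pairs = tuple(ChromosomePair(i, 1.0, 1.2) for i in range(1, 6))
        s = summarize_karyotype(Karyotype("toy", pairs))
        assert s.formula == "10M" and s.fn == 20

    def test_empty_karyotype_rejected(self):
        with pytest.raises(ValueError):
            summarize_karyotype(Karyotype("none", ()))

    def test_recomputed_ar_source_differs_on_boundary_pair(self, table2):
        """LA/SA of the mean arms puts the boundary pair at 1.697 (< 1.70),
        so recomputed mode classifies it metacentric and shifts the formula."""
        s = summarize_karyotype(table2["O. minor"], ar_source="recomputed")
        assert s.formula == "44M+4SM+4ST+8T"

    def test_fundamental_number_published_values(self, table1):
        for row in table1:
            assert fundamental_number(parse_formula(row.formula)) == row.fn

    @pytest.mark.parametrize("counts,expected", [
        ({"M": 14, "SM": 2, "ST": 8, "T": 36}, 76),
        ({"M": 66, "SM": 14, "ST": 10, "T": 2}, 172),
        ({"T": 60}, 60),
    ])
    def test_fundamental_number_examples(self, counts, expected):
        assert fundamental_number(counts) == expected

    def test_fundamental_number_rejects_odd(self):
        with pytest.raises(ValueError):
            fundamental_number({"M": 3})

    def test_formula_round_trip(self, table1):
        for row in table1:
            assert format_formula(parse_formula(row.formula)) == row.formula


class TestProportions:
    def test_pooled_published_percentages(self, table1):
        props = type_proportions([r.summary for r in table1])
        pooled = props["pooled"]
        assert round(pooled[M], 1) == 56.9
        assert round(pooled[SM], 1) == 16.6
        # 102/700 = 14.571: the published figure (14.5) appears truncated
        assert pooled[ST] == pytest.approx(14.571, abs=0.05)
        assert round(pooled[T], 1) == 12.0
        assert abs(sum(round(pooled[c], 1) for c in (M, SM, ST, T)) - 100.0) <= 0.2

    def test_species_percentages(self, table1):
        props = type_proportions([r.summary for r in table1])
        assert round(props["S. lycidas"][M], 1) == 71.7
        assert round(props["O. vulgaris"][T], 1) == 60.0
        assert round(props["O. vulgaris"][M], 1) == 23.3

    def test_group_percentages(self, table1):
        decapods = [r.summary for r in table1 if r.group == "Decapodiformes"]
        pooled = type_proportions(decapods)["pooled"]
        assert round(pooled[M] + pooled[SM], 1) == 77.8

    def test_single_class_is_100(self):
        s = summary_from_formula("toy", "10M")
        assert type_proportions([s])["toy"][M] == 100.0


class TestValidation:
    def test_published_tables_are_clean(self, table2):
        for kt in table2.values():
            assert validate_measurements(kt) == []

    def test_type_mismatch_flagged(self):
        kt = Karyotype("toy", (
            ChromosomePair(1, 1.0, 2.0, reported_ar=2.0, reported_type=ChromosomeClass.M),
        ))
        report = validate_measurements(kt)
        assert len(report) == 1 and "pair 1" in report[0]

    def test_ar_discrepancy_flagged(self):
        kt = Karyotype("toy", (
            ChromosomePair(1, 1.0, 2.0, reported_ar=2.5, reported_type=ChromosomeClass.SM),
        ))
        assert any("differs" in v for v in validate_measurements(kt))
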