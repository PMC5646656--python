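"""Length profiles, λ kernels, the De = −ln λ transform, and dual matrices."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from karyodist import (
    DualMatrix,
    Profile,
    align_profiles,
    build_dual_matrix,
    build_profile,
    de_from_lambda,
    duality_audit,
    lambda_from_de,
    lambda_hamming,
    lambda_ratio,
    lambda_ruzicka,
    matrix_stats,
)

profile_values = st.lists(
    st.floats(min_value=0.05, max_value=10), min_size=1, max_size=20
).map(lambda xs: np.sort(np.array(xs))[::-1])


class TestProfiles:
    def test_published_range(self, table2):
        p = build_profile(table2["O. minor"], mode="none")
        assert p.values[0] == pytest.approx(4.99)
        assert p.values[-1] == pytest.approx(1.15)
        assert len(p.values) == 30

    def test_globally_sorted_across_classes(self, table2):
        # the boundary SM pair (total 4.99) outranks most metacentrics
        v = build_profile(table2["O. minor"], mode="none").values
        assert all(np.diff(v) <= 1e-12)

    @given(profile_values)
    def test_normalization_modes(self, values):
        from karyodist import ChromosomePair, Karyotype
        pairs = tuple(ChromosomePair(i + 1, 0.0, float(v)) for i, v in enumerate(values))
        kt = Karyotype("toy", pairs)
        assert build_profile(kt, "max").values[0] == 1.0
        assert build_profile(kt, "sum").values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_align_zero_pad(self):
        a = Profile("a", np.linspace(3, 1, 30))
        b = Profile("b", np.linspace(3, 1, 46))
        va, vb = align_profiles(a, b, pad="zero")
        assert va.size == vb.size == 46
        assert np.count_nonzero(va == 0) == 16

    def test_align_truncate_and_identity(self):
        a = Profile("a", np.linspace(3, 1, 30))
        b = Profile("b", np.linspace(3, 1, 46))
        va, vb = align_profiles(a, b, pad="truncate")
        assert va.size == vb.size == 30
        va, vb = align_profiles(a, a, pad="zero")
        assert np.array_equal(va, vb)


class TestKernels:
    def test_hamming_hand_example(self):
        assert lambda_hamming([1.0, 0.6, 0.2], [1.0, 0.8, 0.4]) == pytest.approx(
            1 - (0 + 0.2 + 0.2) / 3)

    def test_ratio_hand_example(self):
        assert lambda_ratio([2, 1], [4, 1]) == pytest.approx(0.75)

    def test_ruzicka_proportional(self):
        assert lambda_ruzicka([1, 1], [2, 2]) == pytest.approx(0.5)

    def test_octopod_pair_values(self, table2):
        """Measured-table λ between the two closest octopods, per kernel."""
        om, cc = table2["O. minor"], table2["C. chinensis"]
        am, cm = build_profile(om, "max"), build_profile(cc, "max")
        ar, cr = build_profile(om, "none"), build_profile(cc, "none")
        assert lambda_hamming(*align_profiles(am, cm)) == pytest.approx(0.810, abs=5e-3)
        assert lambda_ratio(*align_profiles(ar, cr)) == pytest.approx(0.829, abs=5e-3)
        assert lambda_ruzicka(*align_profiles(ar, cr)) == pytest.approx(0.805, abs=5e-3)

    @given(profile_values)
    def test_self_similarity_is_one(self, values):
        maxed = values / values[0]
        assert lambda_hamming(maxed, maxed) == 1.0
        assert lambda_ratio(values, values) == 1.0
        assert lambda_ruzicka(values, values) == 1.0

    @given(profile_values, profile_values)
    def test_symmetry_and_bounds(self, a, b):
        n = max(a.size, b.size)
        a = np.pad(a / a[0], (0, n - a.size))
        b = np.pad(b / b[0], (0, n - b.size))
        for kernel in (lambda_hamming, lambda_ratio, lambda_ruzicka):
            lam = kernel(a, b)
            assert kernel(b, a) == lam
            assert 0.0 <= lam <= 1.0

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            lambda_hamming([1.0, 0.5], [1.0])

    def test_zero_padding_never_increases_hamming_lambda(self):
        a = np.array([1.0, 0.6, 0.3])
        b = np.array([1.0, 0.7, 0.4])
        lam_before = lambda_hamming(a, b)
        lam_after = lambda_hamming(np.append(a, 0.0), np.append(b, 0.2))
        assert lam_after <= lam_before


class TestDeTransform:
    @pytest.mark.parametrize("lam,de", [
        (1.0, 0.0),
        (math.exp(-1), 1.0),
        (0.7976, 0.22615),  # published dual cell agrees within 1e-4
    ])
    def test_examples(self, lam, de):
        assert de_from_lambda(lam) == pytest.approx(de, abs=1e-4)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_round_trip(self, lam):
        assert lambda_from_de(de_from_lambda(lam)) == pytest.approx(lam, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1.0), st.floats(min_value=1e-6, max_value=1.0))
    def test_strictly_decreasing(self, l1, l2):
        if l1 < l2:
            assert de_from_lambda(l1) > de_from_lambda(l2)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            de_from_lambda(bad)
        with pytest.raises(ValueError):
            lambda_from_de(-0.5)


class TestDualMatrix:
    def test_three_species_matrix(self, fixtures):
        profiles = [build_profile(k, "none") for k in fixtures.table2]
        dm = build_dual_matrix(profiles, kernel="hamming")
        assert dm.n == 3
        assert np.allclose(dm.lam, dm.lam.T)
        assert dm.get_lam("O. minor", "C. chinensis") == pytest.approx(0.810, abs=5e-3)
        assert dm.get_de("O. minor", "C. chinensis") == pytest.approx(
            -math.log(dm.get_lam("O. minor", "C. chinensis")))

    def test_identical_species_lambda_one(self, fixtures):
        om = build_profile(fixtures.table2[0], "none")
        twin = Profile("twin", om.values, om.mode)
        dm = build_dual_matrix([om, twin])
        assert dm.get_lam("O. minor", "twin") == 1.0
        assert dm.get_de("O. minor", "twin") == 0.0

    def test_duplicate_labels_rejected(self, fixtures):
        om = build_profile(fixtures.table2[0], "none")
        with pytest.raises(ValueError):
            build_dual_matrix([om, om])

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DualMatrix(("a", "b"), de=np.array([[0, 1], [2, 0]]),
                       lam=np.array([[1, 0.5], [0.5, 1]]))

    def test_duality_audit_published(self, table3):
        report = duality_audit(table3)
        assert len(report) == 36
        flagged = sorted((a, b) for a, b, _, bad in report if bad)
        assert flagged == [
            ("C. chinensis", "H. bleekeri"),
            ("S. lessoniana", "H. bleekeri"),
            ("S. lessoniana", "P. edulis"),
        ]

    def test_duality_audit_self_consistent(self, fixtures):
        profiles = [build_profile(k, "none") for k in fixtures.table2]
        dm = build_dual_matrix(profiles)
        assert all(r == pytest.approx(0, abs=1e-12) for _, _, r, _ in duality_audit(dm))

    def test_matrix_stats_published(self, table3):
        stats = matrix_stats(table3)
        assert stats["de"]["min"] == pytest.approx(0.2013)
        assert stats["de"]["max"] == pytest.approx(1.3323)
        assert set(stats["de"]["argmin"]) == {"O. minor", "C. chinensis"}
        assert set(stats["de"]["argmax"]) == {"A. fangsiao", "H. bleekeri"}
        assert stats["lam"]["max"] == pytest.approx(0.8184)
        assert stats["lam"]["min"] == pytest.approx(0.2640)
        # recomputed means differ from the printed ones (0.6742 / 0.5283);
        # the printed values are not reproducible from the printed cells
        assert stats["de"]["mean"] == pytest.approx(0.6850, abs=5e-4)
        assert stats["lam"]["mean"] == pytest.approx(0.5175, abs=5e-4)
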