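"""Collision-correction estimator, saturation model, and their inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qseq import (
    BarcodeConfig,
    SaturationCurve,
    TagCountSummary,
    TagSpaceSaturationError,
    bootstrap_ci,
    estimate_molecules,
    expected_incorporated_tags,
    expected_new_tag_increment,
    expected_observed_tags,
    required_reads,
)

C8 = 65_536


def _summary(s: int, n: int = None, group: str = "g") -> TagCountSummary:
    return TagCountSummary(group_id=group, reads_analyzed=n if n is not None else s,
                           unique_tags_observed=s)


class TestBarcodeConfig:
    @pytest.mark.parametrize("length, space", [(1, 4), (8, 65_536), (9, 262_144)])
    def test_tag_space_is_four_to_the_length(self, length, space):
        assert BarcodeConfig(length).tag_space == space

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_invalid_length_rejected(self, bad):
        with pytest.raises(ValueError):
            BarcodeConfig(bad)


class TestEstimateMolecules:
    # Expected values frozen from a 50-digit arbitrary-precision evaluation
    # of -C*ln(1 - S/C).
    @pytest.mark.parametrize(
        "s, expected",
        [
            (0, 0.0),
            (5_000, 5201.0274380033),
            (41_431, 65547.8175904171),  # S ~ C(1-1/e): estimate ~ C
        ],
    )
    def test_matches_high_precision_oracle(self, barcode8, s, expected):
        est = estimate_molecules(_summary(s), barcode8)
        assert est.estimate == pytest.approx(expected, rel=1e-10)
        assert est.occupancy == pytest.approx(s / C8)

    def test_saturated_tag_space_is_an_error(self, barcode8):
        with pytest.raises(TagSpaceSaturationError):
            estimate_molecules(_summary(C8, n=2 * C8), barcode8)

    def test_non_integer_count_rejected(self, barcode8):
        bad = TagCountSummary.__new__(TagCountSummary)
        object.__setattr__(bad, "group_id", "g")
        object.__setattr__(bad, "reads_analyzed", 10)
        object.__setattr__(bad, "unique_tags_observed", 2.5)
        with pytest.raises(ValueError):
            estimate_molecules(bad, barcode8)

    def test_saturation_warning_threshold(self, barcode8):
        below = estimate_molecules(_summary(int(0.79 * C8)), barcode8)
        above = estimate_molecules(_summary(int(0.81 * C8)), barcode8)
        assert not below.saturation_warning
        assert above.saturation_warning

    @given(st.integers(min_value=0, max_value=C8 - 2))
    @settings(max_examples=60, derandomize=True)
    def test_strictly_increasing_and_dominates_s(self, s):
        barcode = BarcodeConfig(8)
        est = estimate_molecules(_summary(s), barcode)
        est_next = estimate_molecules(_summary(s + 1), barcode)
        assert est_next.estimate > est.estimate
        assert est.estimate >= s

    def test_collision_correction_vanishes_at_low_occupancy(self, barcode8):
        est = estimate_molecules(_summary(50), barcode8)
        assert est.estimate / 50 == pytest.approx(1.0, abs=1e-3)


class TestSaturationModel:
    @pytest.mark.parametrize(
        "h, n, expected",
        [(1, 1, 1.0), (1, 2, 0.0), (2, 2, 0.5)],
    )
    def test_discovery_increment(self, h, n, expected):
        assert expected_new_tag_increment(SaturationCurve(h), n) == expected

    def test_increment_brute_force_simulation(self):
        # P(read 2 is new | H=2 equally likely tags) by direct enumeration of
        # uniform draws: 2 of 4 ordered pairs have a new second tag.
        rng = np.random.default_rng(0)
        draws = rng.integers(0, 2, size=(200_000, 2))
        frac_new = np.mean(draws[:, 0] != draws[:, 1])
        assert frac_new == pytest.approx(0.5, abs=0.01)
        assert expected_new_tag_increment(SaturationCurve(2), 2) == 0.5

    @pytest.mark.parametrize("h", [2, 10, 100, 1000])
    @pytest.mark.parametrize("n", [1, 10, 1_000, 10_000])
    def test_closed_form_equals_partial_sum(self, h, n):
        curve = SaturationCurve(h)
        brute = math.fsum(expected_new_tag_increment(curve, k) for k in range(1, n + 1))
        closed = expected_observed_tags(curve, n)
        assert closed == pytest.approx(brute, rel=1e-9)

    def test_first_read_always_one(self):
        for h in (1, 2, 17, 10_000):
            assert expected_observed_tags(SaturationCurve(h), 1) == 1.0

    def test_large_h_depth_landmark(self):
        # Recovering ~1e5 incorporated tags needs ~1e6 reads; frozen from the
        # closed form H*(1-r^n).
        s = expected_observed_tags(SaturationCurve(100_000), 1_000_000)
        assert s == pytest.approx(99995.4602340192, rel=1e-10)

    def test_single_tag_curve_is_flat(self):
        curve = SaturationCurve(1)
        assert all(expected_observed_tags(curve, n) == 1.0 for n in (1, 10, 10**6))

    @given(st.integers(min_value=2, max_value=10**6), st.integers(min_value=1, max_value=10**6))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_and_bounded_by_h(self, h, n):
        curve = SaturationCurve(h)
        s_n = expected_observed_tags(curve, n)
        assert s_n <= h
        assert expected_observed_tags(curve, n + 1) >= s_n
        assert 0.0 <= expected_new_tag_increment(curve, n + 1) <= expected_new_tag_increment(curve, n)

    @pytest.mark.parametrize("bad_n", [0, -5])
    def test_read_index_must_be_positive(self, bad_n):
        with pytest.raises(ValueError):
            expected_observed_tags(SaturationCurve(10), bad_n)
        with pytest.raises(ValueError):
            expected_new_tag_increment(SaturationCurve(10), bad_n)


class TestRequiredReads:
    def test_half_recovery_of_two_tags_needs_one_read(self):
        assert required_reads(SaturationCurve(2), 0.5) == 1

    def test_agrees_with_linear_scan(self):
        curve = SaturationCurve(1_000)
        target = 0.99 * 1_000
        n = required_reads(curve, 0.99)
        scan = next(k for k in range(1, 10**5) if expected_observed_tags(curve, k) >= target)
        assert n == scan

    @given(st.integers(min_value=2, max_value=10**5),
           st.floats(min_value=0.01, max_value=0.999))
    @settings(max_examples=60, derandomize=True)
    def test_round_trip_definition(self, h, f):
        curve = SaturationCurve(h)
        n = required_reads(curve, f)
        assert expected_observed_tags(curve, n) >= f * h
        if n > 1:
            assert expected_observed_tags(curve, n - 1) < f * h

    def test_full_recovery_rejected(self):
        with pytest.raises(ValueError):
            required_reads(SaturationCurve(10), 1.0)


class TestForwardOccupancy:
    @pytest.mark.parametrize("n, expected", [(0, 0.0), (1, 1.0)])
    def test_degenerate_counts(self, barcode8, n, expected):
        assert expected_incorporated_tags(barcode8, n) == pytest.approx(expected)

    def test_closed_form_frozen_value(self, barcode8):
        # Frozen from 50-digit evaluation of C*(1-(1-1/C)^20000).
        assert expected_incorporated_tags(barcode8, 20_000) == pytest.approx(
            17236.4859081940, rel=1e-10
        )

    def test_monte_carlo_cross_check(self, barcode8):
        # Mean realized distinct-tag count over seeds vs the closed form.
        rng = np.random.default_rng(42)
        reps = 100
        h = [np.unique(rng.integers(0, C8, 20_000)).size for _ in range(reps)]
        se = np.std(h, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(h) - 17236.4859) <= 3 * se

    @pytest.mark.parametrize("n", [100, 1_000, 10_000, 50_000])
    def test_inverse_consistency(self, barcode8, n):
        # -C*ln(1 - E[H]/C) equals N * (-C*ln(1-1/C)) exactly, and the
        # analytic bias factor keeps the round trip within 0.1%.
        h = expected_incorporated_tags(barcode8, n)
        back = -C8 * math.log1p(-h / C8)
        bias_factor = -C8 * math.log1p(-1 / C8)
        assert back == pytest.approx(n * bias_factor, rel=1e-9)
        assert abs(back - n) / n < 1e-3

    def test_negative_templates_rejected(self, barcode8):
        with pytest.raises(ValueError):
            expected_incorporated_tags(barcode8, -1)


class TestBootstrapCI:
    def test_identical_tags_give_degenerate_interval(self, barcode8):
        obs = ["AAAAAAAA"] * 25
        lo, hi = bootstrap_ci(obs, barcode8, replicates=200, seed=1)
        point = estimate_molecules(_summary(1, n=25), barcode8).estimate
        assert lo == hi == pytest.approx(point)

    def test_deterministic_given_seed(self, barcode8):
        rng = np.random.default_rng(5)
        obs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(400)]
        first = bootstrap_ci(obs, barcode8, replicates=200, seed=9)
        second = bootstrap_ci(obs, barcode8, replicates=200, seed=9)
        assert first == second
        assert first[0] <= first[1]

    def test_interval_brackets_point_estimate_scale(self, barcode8):
        rng = np.random.default_rng(8)
        tags = rng.integers(0, C8, 500)
        obs = [f"{t:08d}" for t in tags[rng.integers(0, 500, 5_000)]]
        s = len(set(obs))
        point = estimate_molecules(_summary(s, n=5_000), barcode8).estimate
        lo, hi = bootstrap_ci(obs, barcode8, replicates=300, seed=2)
        assert lo <= point * 1.01 and hi >= point * 0.95

    def test_too_few_replicates_rejected(self, barcode8):
        with pytest.raises(ValueError):
            bootstrap_ci(["AAAAAAAA"], barcode8, replicates=50, seed=0)

    def test_empty_observations_rejected(self, barcode8):
        with pytest.raises(ValueError):
            bootstrap_ci([], barcode8, replicates=200, seed=0)


class TestTagCountSummary:
    def test_tags_cannot_exceed_reads(self):
        with pytest.raises(ValueError):
            TagCountSummary(group_id="g", reads_analyzed=3, unique_tags_observed=4)
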