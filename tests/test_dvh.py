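"""DVH containers, conversions, point metrics and the EQD2 conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geudpred.dvh import (
    CumulativeDVH,
    DVHValidationError,
    EmptyDVHError,
    FractionationScheme,
    cumulative_to_differential,
    differential_to_cumulative,
    dose_at_volume,
    eqd2,
    max_dose,
    mean_dose,
    restrict_above_dose,
    volume_at_dose,
)
from conftest import uniform_cdvh
from helpers import random_cdvh


class TestCumulativeValidation:
    def test_rejects_non_monotone_naming_index(self):
        with pytest.raises(DVHValidationError, match="indices 1 and 2"):
            CumulativeDVH(np.array([0.0, 1.0, 2.0]), np.array([10.0, 5.0, 7.0]))

    def test_rejects_negative_volume(self):
        with pytest.raises(DVHValidationError, match="negative"):
            CumulativeDVH(np.array([0.0, 1.0]), np.array([10.0, -1.0]))

    def test_rejects_nonuniform_spacing(self):
        with pytest.raises(DVHValidationError, match="uniform"):
            CumulativeDVH(np.array([0.0, 1.0, 3.0]), np.array([10.0, 5.0, 0.0]))

    def test_rejects_grid_not_starting_at_zero(self):
        with pytest.raises(DVHValidationError, match="0 Gy"):
            CumulativeDVH(np.array([1.0, 2.0]), np.array([10.0, 0.0]))

    def test_snaps_subtolerance_uptick(self):
        vol = np.array([10.0, 5.0 + 1e-12, 5.0, 0.0])
        cdvh = CumulativeDVH(np.array([0.0, 1.0, 2.0, 3.0]), vol)
        assert np.all(np.diff(cdvh.volume_cc) <= 0)


class TestDifferencing:
    def test_uniform_dose_structure(self):
        cdvh = CumulativeDVH(np.array([0.0, 1.0, 2.0]), np.array([10.0, 10.0, 0.0]))
        ddvh = cumulative_to_differential(cdvh)
        assert np.allclose(ddvh.bin_dose, [0.5, 1.5])
        assert np.allclose(ddvh.bin_volume_cc, [0.0, 10.0])

    def test_residual_tail_kept_in_last_bin(self):
        cdvh = CumulativeDVH(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([8.0, 6.0, 3.0, 1.0])
        )
        ddvh = cumulative_to_differential(cdvh)
        # hand differencing: bins (2, 3, 2) cc plus the 1 cc residual tail
        assert np.allclose(ddvh.bin_volume_cc, [2.0, 3.0, 3.0])
        assert ddvh.total_volume_cc == pytest.approx(8.0, abs=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_volume_conserved_and_roundtrip(self, seed):
        cdvh = random_cdvh(np.random.default_rng(seed))
        ddvh = cumulative_to_differential(cdvh)
        assert ddvh.total_volume_cc == pytest.approx(cdvh.total_volume_cc, rel=1e-12)
        back = differential_to_cumulative(ddvh, cdvh.dose_edges)
        np.testing.assert_allclose(
            back.volume_cc, cdvh.volume_cc, rtol=0, atol=1e-9 * cdvh.total_volume_cc
        )

    def test_roundtrip_exact_on_integer_curve(self):
        cdvh = CumulativeDVH(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([8.0, 6.0, 3.0, 0.0])
        )
        back = differential_to_cumulative(cumulative_to_differential(cdvh), cdvh.dose_edges)
        assert np.array_equal(back.volume_cc, cdvh.volume_cc)


class TestVolumeAtDose:
    def test_v0_is_total_volume(self, ramp_cdvh):
        assert volume_at_dose(ramp_cdvh, 0.0) == ramp_cdvh.total_volume_cc

    def test_linear_interpolation(self, ramp_cdvh):
        assert volume_at_dose(ramp_cdvh, 15.0) == pytest.approx(25.0)

    def test_beyond_last_edge_is_zero(self, ramp_cdvh):
        assert volume_at_dose(ramp_cdvh, 25.0) == 0.0

    def test_relative_mode(self, ramp_cdvh):
        assert volume_at_dose(ramp_cdvh, 10.0, mode="relative") == pytest.approx(0.5)

    def test_negative_dose_rejected(self, ramp_cdvh):
        with pytest.raises(DVHValidationError):
            volume_at_dose(ramp_cdvh, -1.0)

    def test_monotone_non_increasing_in_dose(self, step_cdvh):
        doses = np.linspace(0, 70, 141)
        vols = [volume_at_dose(step_cdvh, d) for d in doses]
        assert np.all(np.diff(vols) <= 1e-12)


class TestDoseAtVolume:
    def test_direct_lookup(self, ramp_cdvh):
        assert dose_at_volume(ramp_cdvh, 50.0) == pytest.approx(10.0)

    def test_inverse_interpolation(self, ramp_cdvh):
        assert dose_at_volume(ramp_cdvh, 25.0) == pytest.approx(15.0)

    def test_total_volume_gets_zero_dose(self, ramp_cdvh):
        assert dose_at_volume(ramp_cdvh, 100.0) == 0.0

    def test_flat_segment_resolved_to_highest_dose(self):
        cdvh = CumulativeDVH(
            np.array([0.0, 10.0, 20.0, 30.0]), np.array([100.0, 50.0, 50.0, 0.0])
        )
        assert dose_at_volume(cdvh, 50.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("bad_volume", [0.0, -5.0, 101.0])
    def test_domain_errors(self, ramp_cdvh, bad_volume):
        with pytest.raises(DVHValidationError):
            dose_at_volume(ramp_cdvh, bad_volume)

    def test_mutual_inverse_on_strictly_decreasing_segment(self, ramp_cdvh):
        for d in (2.5, 7.0, 12.0, 19.0):
            v = volume_at_dose(ramp_cdvh, d)
            assert dose_at_volume(ramp_cdvh, v) == pytest.approx(d)

    def test_max_dose_is_first_zero_edge(self, ramp_cdvh):
        assert max_dose(ramp_cdvh) == pytest.approx(20.0)
        assert max_dose(uniform_cdvh(60.0)) == pytest.approx(61.0)


class TestRestrictAboveDose:
    def test_no_restriction_matches_full_differential(self, step_cdvh):
        full = cumulative_to_differential(step_cdvh)
        sub = restrict_above_dose(step_cdvh, 0.0)
        keep = full.bin_volume_cc > 0
        np.testing.assert_allclose(sub.bin_dose, full.bin_dose[keep])
        np.testing.assert_allclose(
            sub.relative_weights(), full.relative_weights()[keep]
        )

    def test_uniform_structure_single_bin_weight_one(self):
        sub = restrict_above_dose(uniform_cdvh(60.0), 55.0)
        assert sub.bin_dose.size == 1
        assert sub.relative_weights() == pytest.approx([1.0])

    def test_hand_truncation(self, step_cdvh):
        sub = restrict_above_dose(step_cdvh, 40.0)
        assert sub.total_volume_cc == pytest.approx(20.0)
        assert sub.relative_weights().sum() == pytest.approx(1.0)
        assert np.allclose(sub.bin_dose, [50.0])

    def test_partial_bin_split(self, ramp_cdvh):
        sub = restrict_above_dose(ramp_cdvh, 5.0)
        # retained volume must equal V_D exactly
        assert sub.total_volume_cc == pytest.approx(volume_at_dose(ramp_cdvh, 5.0))
        assert sub.bin_dose[0] == pytest.approx(7.5)  # midpoint of (5, 10)

    def test_empty_result_is_valid_value(self, ramp_cdvh):
        sub = restrict_above_dose(ramp_cdvh, 30.0)
        assert sub.is_empty

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 80.0))
    def test_retained_volume_equals_v_d(self, seed, threshold):
        cdvh = random_cdvh(np.random.default_rng(seed))
        sub = restrict_above_dose(cdvh, threshold)
        assert sub.total_volume_cc == pytest.approx(
            volume_at_dose(cdvh, threshold), rel=1e-9, abs=1e-9
        )


class TestMeanDose:
    def test_uniform(self):
        assert mean_dose(restrict_above_dose(uniform_cdvh(60.0), 0.0)) == pytest.approx(60.5)

    def test_symmetric_two_bins(self):
        from geudpred.dvh import DifferentialDVH

        ddvh = DifferentialDVH(np.array([20.0, 60.0]), np.array([5.0, 5.0]))
        assert mean_dose(ddvh) == pytest.approx(40.0)

    def test_empty_signals_undefined(self):
        from geudpred.dvh import DifferentialDVH

        with pytest.raises(EmptyDVHError):
            mean_dose(DifferentialDVH.empty())


class TestEqd2:
    def test_printed_window_conversions(self):
        scheme = FractionationScheme(n_fractions=31, alpha_beta_gy=3.0)
        assert round(eqd2(50.0, scheme)) == 46
        assert round(eqd2(55.0, scheme)) == 53
        assert eqd2(50.0, scheme) == pytest.approx(46.13, abs=0.005)
        assert eqd2(55.0, scheme) == pytest.approx(52.52, abs=0.005)

    def test_two_gy_per_fraction_fixed_point(self):
        scheme = FractionationScheme(n_fractions=31, alpha_beta_gy=3.0)
        assert eqd2(62.0, scheme) == pytest.approx(62.0, rel=1e-12)

    def test_invalid_alpha_beta_rejected(self):
        with pytest.raises(DVHValidationError):
            FractionationScheme(n_fractions=31, alpha_beta_gy=0.0)
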