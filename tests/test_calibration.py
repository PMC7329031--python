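"""Curve parsing, curve mixing, calibration and back-simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodyn.calibration import (
    CalibrationCurve,
    CalibrationError,
    RadiocarbonDate,
    ReservoirCorrection,
    calibrate,
    marine_fraction_from_d13c,
    mix_curves,
    read_calibration_curve,
    uncalibrate,
)

from conftest import make_identity_curve, make_random_smooth_curve, oracle_calibrated_density


class TestReadCurve:
    def test_three_row_file_with_linear_interpolation(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("0,100,5\n100,180,5\n200,300,8\n")
        curve = read_calibration_curve(p)
        assert len(curve.cal_bp) == 3
        assert curve.mu(50.0) == pytest.approx(140.0)
        assert curve.sigma(50.0) == pytest.approx(5.0)

    def test_comment_header_skipped(self, tmp_path):
        p = tmp_path / "curve.txt"
        p.write_text("# cal BP, 14C age, sigma\n0 100 5\n100 180 5\n200 300 8\n")
        curve = read_calibration_curve(p)
        assert curve.mu(50.0) == pytest.approx(140.0)

    def test_query_outside_grid_raises(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("0,100,5\n100,180,5\n200,300,8\n")
        curve = read_calibration_curve(p)
        with pytest.raises(CalibrationError, match="outside curve range"):
            curve.mu(250.0)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("0,100,5\n100,xx,5\n200,300,8\n")
        with pytest.raises(CalibrationError, match=":2"):
            read_calibration_curve(p)

    def test_duplicate_grid_values_rejected(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("0,100,5\n0,110,5\n200,300,8\n")
        with pytest.raises(CalibrationError, match="duplicate"):
            read_calibration_curve(p)

    def test_rows_sorted_ascending(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("200,300,8\n0,100,5\n100,180,5\n")
        curve = read_calibration_curve(p)
        assert np.all(np.diff(curve.cal_bp) > 0)


class TestMixCurves:
    @staticmethod
    def _flat(mu, sd, lo=0, hi=200):
        grid = np.arange(lo, hi + 1, dtype=float)
        return CalibrationCurve(grid, np.full_like(grid, mu), np.full_like(grid, sd))

    def test_fraction_zero_returns_terrestrial_bitwise(self):
        terr, mar = self._flat(1000, 10), self._flat(1400, 10)
        mixed = mix_curves(terr, mar, 0.0, ReservoirCorrection(-83, 34))
        np.testing.assert_array_equal(mixed.mu_14c, terr.mu_14c)
        np.testing.assert_array_equal(mixed.sigma_curve, terr.sigma_curve)

    def test_fraction_one_applies_reservoir_offset(self):
        terr, mar = self._flat(1000, 10), self._flat(1400, 10)
        mixed = mix_curves(terr, mar, 1.0, ReservoirCorrection(-83.0, 34.0))
        np.testing.assert_allclose(mixed.mu_14c, 1400.0 - 83.0)
        np.testing.assert_allclose(mixed.sigma_curve, np.sqrt(10.0**2 + 34.0**2))

    def test_fraction_one_zero_offset_returns_marine_bitwise(self):
        terr, mar = self._flat(1000, 10), self._flat(1400, 10)
        mixed = mix_curves(terr, mar, 1.0, ReservoirCorrection(0.0, 0.0))
        np.testing.assert_array_equal(mixed.mu_14c, mar.mu_14c)
        np.testing.assert_array_equal(mixed.sigma_curve, mar.sigma_curve)

    def test_half_mix_of_constant_curves(self):
        # hand evaluation: mu = 1200, sigma = sqrt(0.25*100 + 0.25*100) = sqrt(50)
        terr, mar = self._flat(1000, 10), self._flat(1400, 10)
        mixed = mix_curves(terr, mar, 0.5, ReservoirCorrection(0.0, 0.0))
        np.testing.assert_allclose(mixed.mu_14c, 1200.0)
        np.testing.assert_allclose(mixed.sigma_curve, np.sqrt(50.0))

    def test_fraction_out_of_range_rejected(self):
        terr, mar = self._flat(1000, 10), self._flat(1400, 10)
        with pytest.raises(CalibrationError):
            mix_curves(terr, mar, 1.2)


class TestCalibrate:
    def test_identity_curve_gives_gaussian_density(self, identity_curve):
        date = RadiocarbonDate("L1", "S1", 1000.0, 50.0)
        dens = calibrate(date, identity_curve)
        assert dens.total == pytest.approx(1.0, abs=1e-9)
        mode_year = dens.cal_bp[np.argmax(dens.density)]
        assert mode_year == 1000
        m = (dens.cal_bp >= 902) & (dens.cal_bp <= 1098)
        assert dens.density[m].sum() == pytest.approx(0.95, abs=0.005)

    def test_flat_curve_gives_uniform_density(self):
        grid = np.arange(0, 501, dtype=float)
        curve = CalibrationCurve(grid, np.full_like(grid, 1000.0), np.zeros_like(grid))
        date = RadiocarbonDate("L1", "S1", 1000.0, 50.0)
        dens = calibrate(date, curve, on_truncation="ignore")
        assert np.ptp(dens.density) < 1e-12

    def test_two_plateaus_give_bimodal_mass_ratio_2_to_1(self):
        # mu sits at 1000 on a 60-yr and a 30-yr plateau; mass ratio ~ 2:1
        grid = np.arange(0, 401, dtype=float)
        mu = np.interp(
            grid, [0, 100, 160, 220, 250, 400], [400, 1000, 1000, 1000, 1000, 1600]
        )
        # separate the plateaus in 14C space by a steep excursion between them
        mu[(grid > 160) & (grid < 220)] = np.interp(
            grid[(grid > 160) & (grid < 220)], [160, 190, 220], [1000, 1450, 1000]
        )
        curve = CalibrationCurve(grid, mu, np.zeros_like(grid))
        date = RadiocarbonDate("L1", "S1", 1000.0, 15.0)
        dens = calibrate(date, curve, on_truncation="ignore")
        mass1 = dens.density[(dens.cal_bp >= 100) & (dens.cal_bp <= 160)].sum()
        mass2 = dens.density[(dens.cal_bp >= 220) & (dens.cal_bp <= 250)].sum()
        assert mass1 / mass2 == pytest.approx(60.0 / 30.0, rel=0.05)
        # this curve's inter-plateau excursion is far steeper than any real
        # curve (15 14C yr/yr), so the quadrature agreement bound is looser
        oracle = oracle_calibrated_density(1000.0, 15.0, curve, dens.cal_bp)
        np.testing.assert_allclose(dens.density, oracle, atol=1e-6)

    def test_matches_bruteforce_oracle_on_synthetic_curve(self, synth_curve):
        date = RadiocarbonDate("L1", "S1", 900.0, 40.0)
        dens = calibrate(date, synth_curve)
        oracle = oracle_calibrated_density(900.0, 40.0, synth_curve, dens.cal_bp)
        assert np.max(np.abs(dens.density - oracle)) < 1e-8

    def test_truncation_at_curve_edge_warns(self):
        curve = make_identity_curve(0, 1020)
        date = RadiocarbonDate("L1", "S1", 1000.0, 50.0)
        with pytest.warns(UserWarning, match="truncated"):
            calibrate(date, curve)

    @settings(max_examples=25, deadline=None)
    @given(
        age=st.floats(min_value=500.0, max_value=1500.0),
        error=st.floats(min_value=15.0, max_value=120.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_density_normalized_and_nonnegative(self, age, error, seed):
        curve = make_random_smooth_curve(np.random.default_rng(seed), step=5)
        dens = calibrate(RadiocarbonDate("L", "S", age, error), curve, on_truncation="ignore")
        assert dens.total == pytest.approx(1.0, abs=1e-9)
        assert np.all(dens.density >= 0)


class TestUncalibrate:
    def test_noise_free_limit_returns_mu(self, identity_curve):
        assert uncalibrate(800.0, identity_curve, 0.0, rng=1) == pytest.approx(800.0)

    def test_same_seed_same_draw(self, synth_curve):
        a = uncalibrate(800.0, synth_curve, 40.0, rng=123)
        b = uncalibrate(800.0, synth_curve, 40.0, rng=123)
        assert a == b

    def test_sample_sd_matches_stated_noise_model(self, synth_curve):
        rng = np.random.default_rng(5)
        draws = np.array([uncalibrate(800.0, synth_curve, 30.0, rng) for _ in range(10_000)])
        expected = np.sqrt(30.0**2 + float(synth_curve.sigma(800.0)) ** 2)
        assert np.std(draws) == pytest.approx(expected, rel=0.05)

    def test_outside_support_raises(self, identity_curve):
        with pytest.raises(CalibrationError):
            uncalibrate(5000.0, identity_curve, 10.0, rng=0)


class TestDateValidation:
    def test_marine_fraction_required_iff_not_terrestrial(self):
        with pytest.raises(CalibrationError):
            RadiocarbonDate("L", "S", 1000, 50, material="marine")
        with pytest.raises(CalibrationError):
            RadiocarbonDate("L", "S", 1000, 50, marine_fraction=0.5)
        d = RadiocarbonDate("L", "S", 1000, 50, material="mixed", marine_fraction=0.4)
        assert d.marine_fraction == 0.4

    @pytest.mark.parametrize("kwargs", [{"error": -1.0}, {"error": 0.0}, {"age_14c": -5.0}])
    def test_invalid_numbers_rejected(self, kwargs):
        base = {"lab_id": "L", "site_id": "S", "age_14c": 1000.0, "error": 50.0}
        with pytest.raises(CalibrationError):
            RadiocarbonDate(**{**base, **kwargs})


def test_marine_fraction_from_d13c_endmembers():
    assert marine_fraction_from_d13c(-21.0) == 0.0
    assert marine_fraction_from_d13c(-12.0) == 1.0
    assert marine_fraction_from_d13c(-16.5) == pytest.approx(0.5)
    assert marine_fraction_from_d13c(-25.0) == 0.0  # clipped
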