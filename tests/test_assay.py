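"""Standard-curve calibration, inversion and release profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelscreen import (DiscSpec, EluateSeries, WellCondition,
                       fit_standard_curve, invert_curve, release_profile,
                       sample_eluates, simulate_kinetics)
from gelscreen.assay import read_eluates, release_profiles
from oracles import ols_line

SLOPE, INTERCEPT = 0.02, 0.05


class TestFitStandardCurve:
    def test_exact_line_recovered(self):
        concs = [0.0, 25.0, 50.0, 100.0]
        standards = [(c, 0.002 * c + 0.10) for c in concs]
        curve = fit_standard_curve(standards)
        assert curve.slope == pytest.approx(0.002)
        assert curve.intercept == pytest.approx(0.10)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.valid_range == (0.0, 100.0)

    def test_two_standards_pass_through_both_points(self):
        curve = fit_standard_curve([(10.0, 0.3), (50.0, 1.1)])
        assert curve.predict(10.0) == pytest.approx(0.3)
        assert curve.predict(50.0) == pytest.approx(1.1)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        conc = np.linspace(0, 100, 12)
        ab = 0.015 * conc + 0.07 + rng.normal(0, 0.01, conc.size)
        curve = fit_standard_curve(list(zip(conc, ab)))
        slope, intercept = ols_line(conc, ab)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_standard_curve([(5.0, 0.1), (5.0, 0.2), (5.0, 0.3)])

    def test_single_standard_rejected(self):
        with pytest.raises(ValueError, match="two standards"):
            fit_standard_curve([(5.0, 0.1)])


class TestInvertCurve:
    curve = fit_standard_curve([(c, SLOPE * c + INTERCEPT)
                                for c in (0.0, 50.0, 100.0)])

    def test_absorbance_at_intercept_maps_to_zero(self):
        conc, flag = invert_curve(self.curve, INTERCEPT)
        assert conc == pytest.approx(0.0, abs=1e-12)
        assert not flag  # 0 is inside the calibrated range

    def test_midrange_inversion(self):
        conc, flag = invert_curve(self.curve, SLOPE * 50 + INTERCEPT)
        assert conc == pytest.approx(50.0)
        assert not flag

    def test_extrapolation_flagged_and_clamped(self):
        conc, flag = invert_curve(self.curve, SLOPE * 150 + INTERCEPT)
        assert flag and conc == pytest.approx(150.0)
        conc, flag = invert_curve(self.curve, INTERCEPT - 0.1)
        assert flag and conc == 0.0  # clamped below at zero

    def test_zero_slope_rejected(self):
        from gelscreen import StandardCurve

        flat = StandardCurve(slope=0.0, intercept=0.1, r_squared=0.0,
                             valid_range=(0.0, 10.0))
        with pytest.raises(ValueError, match="slope"):
            invert_curve(flat, 0.5)

    def test_fit_predict_invert_round_trip_on_standards(self):
        concs = np.array([0.0, 5.0, 20.0, 60.0, 100.0])
        curve = fit_standard_curve([(c, SLOPE * c + INTERCEPT) for c in concs])
        for c in concs:
            back, _ = invert_curve(curve, curve.predict(c))
            assert back == pytest.approx(c, abs=1e-9 * max(1.0, c))

    @given(a1=st.floats(0.06, 1.0), a2=st.floats(0.06, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strictly_monotone_for_positive_slope(self, a1, a2):
        c1, _ = invert_curve(self.curve, a1)
        c2, _ = invert_curve(self.curve, a2)
        if a1 < a2:
            assert c1 < c2


def _kinetics_truth(concs, seed=0, duration=17.0):
    wells = [WellCondition(f"W{i}", c) for i, c in enumerate(concs)]
    return simulate_kinetics(wells, DiscSpec(), duration=duration, step=0.25,
                             seed=seed)


class TestReleaseProfile:
    curve = fit_standard_curve([(c, SLOPE * c + INTERCEPT)
                                for c in (0.0, 25.0, 50.0, 75.0, 100.0)])

    def test_blank_absorbances_give_zero_mass(self):
        series = EluateSeries("A", times=[0, 1, 2], absorbance=[INTERCEPT] * 3)
        out = release_profile(series, self.curve, reservoir_vol=20.0)
        np.testing.assert_allclose(out["cum_mass_ug"], 0.0, atol=1e-12)

    def test_mass_scales_linearly_with_reservoir_volume(self):
        ab = [0.1, 0.2, 0.4]
        a = release_profile(EluateSeries("A", [0, 1, 2], ab), self.curve, 10.0)
        b = release_profile(EluateSeries("A", [0, 1, 2], ab), self.curve, 30.0)
        np.testing.assert_allclose(b["cum_mass_ug"], 3.0 * a["cum_mass_ug"])

    def test_nonmonotone_profile_logged_not_rejected(self, caplog):
        series = EluateSeries("A", [0, 1, 2], [0.3, 0.5, 0.4])
        with caplog.at_level("WARNING"):
            out = release_profile(series, self.curve, 20.0)
        assert len(out) == 3
        assert any("non-monotone" in r.message for r in caplog.records)

    def test_noisy_eluates_recover_simulated_release_within_10pct(self):
        """Release recovered from noisy absorbances stays within 10% of the
        simulated cumulative release wherever truth >= 20% of the load."""
        truth = _kinetics_truth([0.0, 200.0], seed=5)
        times = [0.0, 1.0, 2.0, 3.0, 17.0]
        vol = 20.0
        eluates = sample_eluates(truth, times, SLOPE, INTERCEPT, vol,
                                 noise_sd=0.005, seed=23)
        for wid, grp in eluates.groupby("well_id", sort=False):
            series = EluateSeries(str(wid), grp["time_h"].to_numpy(),
                                  grp["absorbance"].to_numpy())
            out = release_profile(series, self.curve, vol)
            j = truth.column(str(wid))
            true_cum = np.interp(times, truth.times, truth.cum_pva[:, j])
            for got, want in zip(out["cum_mass_ug"], true_cum):
                if want >= 0.2 * truth.disc.pva_load:
                    assert abs(got - want) / want <= 0.10

    def test_enzyme_condition_releases_at_least_as_much(self):
        """With enzyme the final recovered release is >= without; both show
        a nonzero early burst at 1 h."""
        truth = _kinetics_truth([0.0, 200.0], seed=5)
        times = [0.0, 1.0, 2.0, 3.0, 17.0]
        eluates = sample_eluates(truth, times, SLOPE, INTERCEPT, 20.0,
                                 noise_sd=0.005, seed=31)
        finals, bursts = {}, {}
        for wid, grp in eluates.groupby("well_id", sort=False):
            series = EluateSeries(str(wid), grp["time_h"].to_numpy(),
                                  grp["absorbance"].to_numpy())
            out = release_profile(series, self.curve, 20.0)
            finals[str(wid)] = float(out["cum_mass_ug"].iloc[-1])
            bursts[str(wid)] = float(out["cum_mass_ug"].iloc[1])
        assert finals["W1"] >= finals["W0"]  # W1 carries the enzyme
        assert bursts["W0"] > 0 and bursts["W1"] > 0


def test_eluates_csv_round_trip(tmp_path):
    truth = _kinetics_truth([100.0], seed=2, duration=4.0)
    df = sample_eluates(truth, [0.0, 1.0, 3.0], SLOPE, INTERCEPT, 20.0,
                        noise_sd=0.0, seed=0)
    path = tmp_path / "eluates.csv"
    df.to_csv(path, index=False)
    series = read_eluates(path)
    assert [s.well_id for s in series] == ["W0"]
    np.testing.assert_allclose(series[0].absorbance, df["absorbance"])
    curve = fit_standard_curve([(c, SLOPE * c + INTERCEPT)
                                for c in (0.0, 50.0, 100.0)])
    out = release_profiles(series, curve, 20.0)
    j = truth.column("W0")
    true_cum = np.interp([0.0, 1.0, 3.0], truth.times, truth.cum_pva[:, j])
    np.testing.assert_allclose(out["cum_mass_ug"], true_cum, atol=1e-6)
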