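"""Kinetics simulator and frame renderer against closed forms and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelscreen import (DiscSpec, RenderConfig, Well, WellCondition,
                       WellLayout, render_frames, simulate_kinetics)
from oracles import circle_pixel_count


def _single_well(conds=None, disc=None, **kin):
    conds = conds or [WellCondition("A", 0.0)]
    disc = disc or DiscSpec()
    defaults = dict(duration=10.0, step=0.5, seed=0)
    defaults.update(kin)
    return simulate_kinetics(conds, disc, **defaults)


class TestKinetics:
    def test_zero_rate_zero_burst_is_static(self):
        disc = DiscSpec(burst_frac=0.0)
        truth = _single_well(disc=disc)
        assert np.all(truth.radius == disc.radius0)
        assert np.all(truth.cum_pva == 0.0)
        assert np.all(truth.cum_gel == 0.0)
        assert truth.t_complete["A"] is None

    def test_closed_form_completion_time_and_area_fraction(self):
        # erosion speed 0.2 mm/h on a 2 mm disc: gone at 10 h, area
        # fraction (1 - 0.5)^2 = 0.25 at 5 h
        cond = WellCondition("A", enzyme_conc=100.0, erode_coeff=0.002)
        truth = _single_well([cond], duration=12.0, step=0.5)
        assert truth.t_complete["A"] == pytest.approx(10.0)
        i5 = int(np.argmin(np.abs(truth.times - 5.0)))
        frac = truth.area_mm2[i5, 0] / truth.area_mm2[0, 0]
        assert frac == pytest.approx(0.25)

    def test_closed_form_burst_release(self):
        disc = DiscSpec(burst_frac=1.0, burst_tau=1.0, pva_load=100.0)
        truth = _single_well(disc=disc, duration=4.0, step=0.25)
        i1 = int(np.argmin(np.abs(truth.times - 1.0)))
        assert truth.cum_pva[i1, 0] == pytest.approx(100.0 * (1 - math.e ** -1))

    @pytest.mark.parametrize("duration,step", [(0.0, 1.0), (-1.0, 1.0),
                                               (10.0, 0.0), (10.0, -0.5)])
    def test_nonpositive_duration_or_step_rejected(self, duration, step):
        with pytest.raises(ValueError, match="positive"):
            simulate_kinetics([WellCondition("A", 0.0)], DiscSpec(),
                              duration=duration, step=step, seed=0)

    @given(conc=st.floats(0.0, 300.0),
           burst_frac=st.floats(0.0, 1.0),
           burst_tau=st.floats(0.1, 5.0),
           seed=st.integers(0, 2 ** 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_and_release_bounds(self, conc, burst_frac,
                                             burst_tau, seed):
        disc = DiscSpec(burst_frac=burst_frac, burst_tau=burst_tau)
        cond = WellCondition("A", conc, disintegrate_frac=0.5,
                             disintegrate_prob=0.3)
        truth = simulate_kinetics([cond], disc, duration=20.0, step=0.5,
                                  seed=seed)
        r = truth.radius[:, 0]
        assert np.all(np.diff(r) <= 1e-12)  # radius non-increasing
        np.testing.assert_allclose(truth.area_mm2, math.pi * truth.radius ** 2)
        np.testing.assert_allclose(
            truth.cum_gel + truth.mass,
            np.broadcast_to(truth.mass[0:1, :], truth.mass.shape))
        pva = truth.cum_pva[:, 0]
        assert np.all(np.diff(pva) >= -1e-9)
        assert pva.max() <= disc.pva_load * (1 + 1e-12)

    def test_higher_enzyme_degrades_no_slower(self):
        conds = [WellCondition("lo", 50.0), WellCondition("hi", 200.0)]
        truth = simulate_kinetics(conds, DiscSpec(), duration=20.0,
                                  step=0.5, seed=0)
        assert np.all(truth.radius[:, 1] <= truth.radius[:, 0])
        t_lo, t_hi = truth.t_complete["lo"], truth.t_complete["hi"]
        if t_lo is not None and t_hi is not None:
            assert t_hi <= t_lo

    def test_disintegration_truncates_radius_and_sets_event_time(self):
        cond = WellCondition("A", 100.0, disintegrate_frac=0.5,
                             disintegrate_prob=1.0)
        truth = _single_well([cond], duration=20.0, step=0.25)
        t_event = truth.disintegrated_at["A"]
        assert t_event is not None
        i = int(np.argmin(np.abs(truth.times - t_event)))
        assert np.all(truth.radius[i:, 0] == 0.0)
        assert truth.radius[i - 1, 0] > 0.0
        # the event can only fire once area fraction < disintegrate_frac
        frac_before = (truth.radius[i - 1, 0] / DiscSpec().radius0) ** 2
        assert frac_before < 0.5 + 0.1  # crossed (or near) the gate
        assert truth.t_complete["A"] == t_event

    def test_same_seed_reproduces_kinetics(self):
        cond = WellCondition("A", 200.0, disintegrate_frac=0.6,
                             disintegrate_prob=0.4)
        a = _single_well([cond], duration=20.0, step=0.25, seed=42)
        b = _single_well([cond], duration=20.0, step=0.25, seed=42)
        np.testing.assert_array_equal(a.radius, b.radius)
        assert a.disintegrated_at == b.disintegrated_at


def _static_render(radius_mm, px_per_mm, **cfg_kw):
    """Render a static disc of the given radius in a 101x101 single well."""
    disc = DiscSpec(radius0=radius_mm)
    truth = simulate_kinetics([WellCondition("A", 0.0)], disc,
                              duration=1.0, step=1.0, seed=0)
    layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=45.0)])
    cfg = RenderConfig(px_per_mm=px_per_mm, image_size=(101, 101),
                       noise_sd=0.0, debris_rate=0.0, seed=5, **cfg_kw)
    return render_frames(truth, layout, cfg), cfg


class TestRenderer:
    def test_disc_pixel_count_matches_brute_force_oracle(self):
        (frames, manifest), cfg = _static_render(radius_mm=2.0, px_per_mm=15.0)
        img = frames[0].pixels
        count = int(np.all(img == cfg.disc_color, axis=-1).sum())
        assert count == circle_pixel_count((101, 101), 50.5, 50.5, 30.0)

    def test_zero_radius_truth_renders_no_disc_pixels(self):
        disc = DiscSpec(radius0=2.0)
        cond = WellCondition("A", 1000.0, erode_coeff=1.0)  # gone by t=step
        truth = simulate_kinetics([cond], disc, duration=2.0, step=1.0, seed=0)
        truth.radius[:] = 0.0
        truth.area_mm2[:] = 0.0
        layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=45.0)])
        cfg = RenderConfig(px_per_mm=15.0, image_size=(101, 101),
                           noise_sd=0.0, debris_rate=0.0, seed=0)
        frames, _ = render_frames(truth, layout, cfg)
        for f in frames:
            assert not np.all(f.pixels == cfg.disc_color, axis=-1).any()

    def test_same_seed_renders_bit_identical_frames(self):
        truth = simulate_kinetics([WellCondition("A", 100.0)], DiscSpec(),
                                  duration=4.0, step=1.0, seed=3)
        layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=45.0)])
        cfg = RenderConfig(px_per_mm=15.0, image_size=(101, 101),
                           noise_sd=4.0, debris_rate=2.0, seed=9)
        a, _ = render_frames(truth, layout, cfg)
        b, _ = render_frames(truth, layout, cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_disc_larger_than_well_rejected(self):
        truth = simulate_kinetics([WellCondition("A", 0.0)],
                                  DiscSpec(radius0=4.0), duration=1.0,
                                  step=1.0, seed=0)
        layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=45.0)])
        cfg = RenderConfig(px_per_mm=15.0, image_size=(101, 101), seed=0)
        with pytest.raises(ValueError, match="exceeds well radius"):
            render_frames(truth, layout, cfg)

    def test_well_outside_image_rejected(self):
        truth = simulate_kinetics([WellCondition("A", 0.0)], DiscSpec(),
                                  duration=1.0, step=1.0, seed=0)
        layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=60.0)])
        cfg = RenderConfig(px_per_mm=15.0, image_size=(101, 101), seed=0)
        with pytest.raises(ValueError, match="fit"):
            render_frames(truth, layout, cfg)

    def test_manifest_times_follow_frame_interval(self):
        (frames, manifest), cfg = _static_render(radius_mm=1.0, px_per_mm=10.0)
        assert list(manifest.columns) == ["filename", "time_min"]
        assert manifest["time_min"].tolist() == [0.0, 60.0]

    def test_debris_lands_outside_wells_only(self):
        truth = simulate_kinetics([WellCondition("A", 0.0)], DiscSpec(),
                                  duration=1.0, step=1.0, seed=0)
        layout = WellLayout([Well("A", cx=50.5, cy=50.5, r=45.0)])
        cfg = RenderConfig(px_per_mm=15.0, image_size=(101, 101),
                           noise_sd=0.0, debris_rate=30.0, debris_size_px=6,
                           seed=21)
        frames, _ = render_frames(truth, layout, cfg)
        yy, xx = np.mgrid[:101, :101]
        in_well = (yy - 50.5) ** 2 + (xx - 50.5) ** 2 <= 45.0 ** 2
        for f in frames:
            disc_px = np.all(f.pixels == cfg.disc_color, axis=-1)
            outside = disc_px & ~in_well
            # all disc-colored pixels outside the well are debris; inside the
            # well only the true disc appears
            inside_count = int((disc_px & in_well).sum())
            assert inside_count == circle_pixel_count((101, 101), 50.5, 50.5,
                                                      30.0)
            assert outside.sum() > 0  # debris did appear at rate 30
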