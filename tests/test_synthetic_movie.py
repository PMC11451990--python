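"""Simulator: geometry construction, event statistics, rendering, determinism."""

import numpy as np
import pytest

from cmekymo.core import ConfigError, substream
from cmekymo.synthetic_movie import (
    CompartmentParams,
    SimulationConfig,
    event_frame_span,
    events_to_dataframe,
    make_cell_geometry,
    sample_events,
    simulate,
)


class TestConfig:
    def test_zero_daughter_radius_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(daughter_radius_px=0)

    def test_non_touching_lobes_rejected(self):
        with pytest.raises(ConfigError, match="does not touch"):
            SimulationConfig(center_distance_px=100.0)

    def test_cv_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(daughter=CompartmentParams(rate_per_um_min=1.0, lifetime_cv=1.5))


class TestGeometry:
    def test_two_touching_lobes_mother_larger(self):
        geom = make_cell_geometry(SimulationConfig(mother_radius_px=30, daughter_radius_px=15))
        labels, counts = np.unique(geom.label_mask[geom.label_mask > 0], return_counts=True)
        assert list(labels) == [1, 2]
        assert counts[0] > counts[1]
        # lobes touch: some mother pixel is 8-adjacent to a daughter pixel
        from scipy.ndimage import binary_dilation

        touch = binary_dilation(geom.label_mask == 1, np.ones((3, 3))) & (geom.label_mask == 2)
        assert touch.any()

    def test_truth_contour_lengths_match_circle_analytics(self):
        cfg = SimulationConfig()
        geom = make_cell_geometry(cfg)
        for name, radius in (("mother", 30.0), ("daughter", 15.0)):
            c = geom.contours[name]
            assert c.total_length_px == pytest.approx(2 * np.pi * radius, rel=0.01)
            assert 0 < c.retained_length_px < c.total_length_px

    def test_neck_arc_excluded_from_truth_contours(self):
        cfg = SimulationConfig()
        geom = make_cell_geometry(cfg)
        # excluded mother samples lie inside (or near) the daughter disk region
        c = geom.contours["mother"]
        exc = c.points[c.excluded]
        d = np.hypot(exc[:, 0] - geom.daughter_center[0], exc[:, 1] - geom.daughter_center[1])
        assert (d <= cfg.daughter_radius_px + cfg.neck_margin_px + c.step_px).all()


class TestSampleEvents:
    def test_zero_rates_give_zero_events(self):
        cfg = SimulationConfig(
            mother=CompartmentParams(rate_per_um_min=0.0),
            daughter=CompartmentParams(rate_per_um_min=0.0),
        )
        geom = make_cell_geometry(cfg)
        assert sample_events(cfg, geom) == []

    def test_event_count_expectation_within_3_se(self):
        """Mean in-window event count tracks rate x length x duration."""
        cfg = SimulationConfig(
            mother=CompartmentParams(rate_per_um_min=0.4),
            daughter=CompartmentParams(rate_per_um_min=2.0),
        )
        geom = make_cell_geometry(cfg)
        n_rep = 60
        counts = {"mother": [], "daughter": []}
        for i in range(n_rep):
            events = sample_events(cfg, geom, substream(100 + i, "t"))
            for comp in counts:
                counts[comp].append(
                    sum(1 for e in events if e.compartment == comp and e.t_birth_s >= 0)
                )
        for comp in counts:
            lam = (
                cfg.compartment(comp).rate_per_um_min
                * geom.contours[comp].retained_length_um
                * cfg.duration_s
                / 60.0
            )
            mean = np.mean(counts[comp])
            se = np.sqrt(lam / n_rep)
            assert abs(mean - lam) < 3 * se

    def test_rate_ratio_reflected_in_counts(self):
        cfg = SimulationConfig(
            mother=CompartmentParams(rate_per_um_min=0.5),
            daughter=CompartmentParams(rate_per_um_min=2.5),
            duration_s=600.0,
        )
        geom = make_cell_geometry(cfg)
        n = {"mother": 0, "daughter": 0}
        for i in range(30):
            for e in sample_events(cfg, geom, substream(i, "ratio")):
                if e.t_birth_s >= 0:
                    n[e.compartment] += 1
        dens_d = n["daughter"] / geom.contours["daughter"].retained_length_um
        dens_m = n["mother"] / geom.contours["mother"].retained_length_um
        assert dens_d / dens_m == pytest.approx(5.0, rel=0.15)

    def test_boundary_event_censored_both_ends(self):
        first, last = event_frame_span(-10.0, 200.0, 180, 1.0)
        assert (first, last) == (0, 179)

    def test_interior_event_not_censored(self):
        first, last = event_frame_span(10.2, 40.2, 180, 1.0)
        assert (first, last) == (11, 40)  # 30 visible frames

    def test_lifetimes_truncated_at_two_frames(self):
        cfg = SimulationConfig(
            daughter=CompartmentParams(rate_per_um_min=5.0, lifetime_mean_s=4.0, lifetime_cv=0.9,
                                       lifetime_family="lognormal")
        )
        geom = make_cell_geometry(cfg)
        events = sample_events(cfg, geom)
        assert all(e.t_death_s - e.t_birth_s >= 2 * cfg.frame_interval_s for e in events)

    def test_ground_truth_table_deterministic(self):
        cfg = SimulationConfig(seed=42)
        geom = make_cell_geometry(cfg)
        df1 = events_to_dataframe(sample_events(cfg, geom))
        df2 = events_to_dataframe(sample_events(cfg, geom))
        assert df1.equals(df2)


class TestRender:
    def test_background_mean_without_events(self):
        cfg = SimulationConfig(
            mother=CompartmentParams(rate_per_um_min=0.0),
            daughter=CompartmentParams(rate_per_um_min=0.0),
            background=10.0,
            cell_background=10.0,
            read_noise_sd=0.0,
            duration_s=20.0,
            seed=3,
        )
        result = simulate(cfg)
        mean = result.stacks[1].pixels.mean()
        assert mean == pytest.approx(10.0, abs=3 * np.sqrt(10.0 / result.stacks[1].pixels.size))

    def test_plateau_event_peak_amplitude_noiseless(self):
        cfg = SimulationConfig(
            daughter=CompartmentParams(rate_per_um_min=0.3, amplitude=50.0),
            mother=CompartmentParams(rate_per_um_min=0.0),
            duration_s=60.0,
            seed=8,
        )
        result = simulate(cfg, noise=False)
        events = [e for e in result.events if e.compartment == "daughter"]
        assert events
        e = events[0]
        frame = result.stacks[1].pixels[(e.first_frame + e.last_frame) // 2]
        iy, ix = int(round(e.y_px)), int(round(e.x_px))
        local_bg = cfg.cell_background
        peak = frame[iy - 1 : iy + 2, ix - 1 : ix + 2].max()
        # sub-pixel offset attenuates the brightest pixel by at most ~12%
        assert 0.85 * e.amplitude <= peak - local_bg * 0.2 <= 1.05 * e.amplitude + local_bg

    def test_bleaching_decay_recovered_from_background(self):
        cfg = SimulationConfig(
            mother=CompartmentParams(rate_per_um_min=0.0),
            daughter=CompartmentParams(rate_per_um_min=0.0),
            bleach_rate_per_s=0.01,
            read_noise_sd=0.0,
            duration_s=120.0,
            seed=5,
        )
        result = simulate(cfg)
        means = result.stacks[1].pixels.mean(axis=(1, 2))
        t = np.arange(len(means))
        rate = -np.polyfit(t, np.log(means), 1)[0]
        assert rate == pytest.approx(0.01, rel=0.05)

    def test_calibration_carried_through(self):
        cfg = SimulationConfig(pixel_size_nm=65.0, frame_interval_s=1.0, duration_s=10.0)
        result = simulate(cfg)
        stack = result.stacks[1]
        assert stack.pixel_size_nm == 65.0 and stack.frame_interval_s == 1.0

    def test_two_channel_offset_creates_twin_events(self):
        cfg = SimulationConfig(channel_offset_s=(5.0, 5.0), duration_s=60.0, seed=9)
        result = simulate(cfg)
        df = result.events_table
        ch1 = df[(df.channel == 1) & df.compartment.isin(["mother", "daughter"])]
        ch2 = df[df.channel == 2]
        assert len(ch2) >= 0.8 * len(ch1)  # twins near the movie end may fall outside
        merged = ch1.merge(ch2, on=["arclength_um", "compartment"], suffixes=("_1", "_2"))
        assert np.allclose(merged.t_birth_s_2 - merged.t_birth_s_1, 5.0)

    def test_rendering_deterministic(self):
        cfg = SimulationConfig(seed=12, duration_s=15.0)
        a = simulate(cfg).stacks[1].pixels
        b = simulate(cfg).stacks[1].pixels
        assert np.array_equal(a, b)
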