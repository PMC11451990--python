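"""Trace detection, lifetime summaries, Mann-Whitney, two-stage split,
and two-channel alignment — each checked against an independent oracle
where the spec of the operation allows one."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from cmekymo.core import ConfigError
from cmekymo.kymograph import Kymograph
from cmekymo.trace_quant import (
    Trace,
    align_traces,
    detect_traces,
    estimate_baseline,
    mann_whitney,
    split_two_stage,
    summarize_lifetimes,
)
from cmekymo.validation import flood_fill_traces_reference, synthetic_step_trace


def make_kymo(values, adjacent=None):
    values = np.asarray(values, dtype=float)
    s = values.shape[0]
    adj = np.ones(s, dtype=bool) if adjacent is None else np.asarray(adjacent, dtype=bool)
    return Kymograph(
        values=values,
        row_arclength_um=np.arange(s) * 0.065,
        adjacent_next=adj,
        pixel_size_nm=65.0,
        frame_interval_s=1.0,
    )


class TestBaseline:
    def test_constant_kymograph(self):
        baseline, noise = estimate_baseline(make_kymo(np.full((10, 30), 3.0)))
        assert np.allclose(baseline, 3.0) and noise == 0.0

    def test_median_robust_to_short_event(self):
        values = np.full((5, 180), 10.0)
        values[2, 50:60] = 100.0  # 10 of 180 frames
        baseline, _ = estimate_baseline(make_kymo(values))
        assert baseline[2] == 10.0

    def test_mad_recovers_gaussian_sigma(self):
        rng = np.random.default_rng(0)
        values = 50.0 + rng.normal(0, 2.0, size=(40, 200))
        _, noise = estimate_baseline(make_kymo(values))
        assert noise == pytest.approx(2.0, rel=0.10)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConfigError):
            estimate_baseline(make_kymo(np.zeros((4, 4))))


class TestDetect:
    def _sets(self, traces):
        return sorted(
            (tuple(sorted(tr.rows)), tr.t_start, tr.t_end) for tr in traces
        )

    def test_seam_straddling_event_counted_once(self):
        values = np.zeros((10, 20))
        values[[8, 9, 0, 1], 5:10] = 10.0
        traces = detect_traces(make_kymo(values), k_sigma=4, min_len_frames=3,
                               baseline=np.zeros(10), noise=1.0)
        assert len(traces) == 1
        assert set(traces[0].rows) == {0, 1, 8, 9}

    def test_excluded_gap_separates_components(self):
        values = np.zeros((10, 20))
        values[[3, 4], 5:10] = 10.0  # rows 3-4 adjacent...
        adj = np.ones(10, dtype=bool)
        adj[3] = False  # ...but a neck gap lies between them
        traces = detect_traces(make_kymo(values, adj), k_sigma=4, min_len_frames=3,
                               baseline=np.zeros(10), noise=1.0)
        assert len(traces) == 2

    def test_sub_threshold_frame_separates_same_row_events(self):
        values = np.zeros((6, 30))
        values[2, 5:10] = 10.0
        values[2, 11:16] = 10.0  # one silent frame between
        traces = detect_traces(make_kymo(values), k_sigma=4, min_len_frames=3,
                               baseline=np.zeros(6), noise=1.0)
        assert len(traces) == 2

    def test_whole_movie_event_censored_both_ends(self):
        values = np.zeros((6, 30))
        values[3, :] = 10.0
        (tr,) = detect_traces(make_kymo(values), baseline=np.zeros(6), noise=1.0)
        assert tr.censored_start and tr.censored_end

    def test_short_components_filtered(self):
        values = np.zeros((6, 30))
        values[1, 4:6] = 10.0  # 2 frames < min_len 3
        traces = detect_traces(make_kymo(values), min_len_frames=3,
                               baseline=np.zeros(6), noise=1.0)
        assert traces == []

    def test_zero_noise_zero_signal_empty(self):
        assert detect_traces(make_kymo(np.full((6, 30), 2.0))) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_flood_fill(self, seed):
        """Connected components match a pure-python flood fill on random
        thresholded maps with random seam/gap adjacency."""
        rng = np.random.default_rng(seed)
        s, t = rng.integers(8, 50), rng.integers(8, 50)
        binary = rng.uniform(size=(s, t)) < 0.25
        adj = rng.uniform(size=s) < 0.8
        values = binary.astype(float) * 10.0
        kymo = make_kymo(values, adj)
        traces = detect_traces(kymo, k_sigma=4, min_len_frames=1, min_rows=1,
                               baseline=np.zeros(s), noise=1.0)
        ref = flood_fill_traces_reference(binary, adj)
        ref_sets = sorted(
            (tuple(sorted({r for r, _ in comp})), min(c for _, c in comp), max(c for _, c in comp))
            for comp in ref
        )
        assert self._sets(traces) == ref_sets


class TestSummaries:
    def _trace(self, lifetime_s, censored=False):
        n = int(lifetime_s)
        return Trace(rows=np.array([0]), t_start=10, t_end=10 + n - 1, frame_interval_s=1.0,
                     censored_start=censored, censored_end=False,
                     intensity_profile=np.ones(n), peak=1.0)

    def test_hand_computed_moments(self):
        traces = [self._trace(s) for s in (28, 30, 32)]
        s = summarize_lifetimes(traces, retained_length_um=10.0, duration_min=3.0)
        assert s.mean_s == pytest.approx(30.0)
        assert s.sd_s == pytest.approx(2.0)
        assert s.cv_percent == pytest.approx(100 * 2.0 / 30.0, abs=0.05)

    def test_frequency_normalisation(self):
        traces = [self._trace(10) for _ in range(12)]
        s = summarize_lifetimes(traces, retained_length_um=15.0, duration_min=3.0)
        assert s.frequency_per_um_min == pytest.approx(12 / 45.0)

    def test_all_censored_gives_nan_moments_but_frequency(self):
        traces = [self._trace(10, censored=True) for _ in range(4)]
        s = summarize_lifetimes(traces, retained_length_um=10.0, duration_min=2.0)
        assert math.isnan(s.mean_s) and s.n_censored == 4
        assert s.frequency_per_um_min == pytest.approx(4 / 20.0)

    def test_include_flagged_policy_uses_censored(self):
        traces = [self._trace(10), self._trace(30, censored=True)]
        s = summarize_lifetimes(traces, 10.0, 3.0, censor_policy="include-flagged")
        assert s.mean_s == pytest.approx(20.0)


def brute_force_mw_p(x, y):
    """Oracle: exhaustive relabeling, U by direct pair counting."""
    combined = list(x) + list(y)
    n1 = len(x)

    def u_of(sample_x, sample_y):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in sample_x for b in sample_y)

    u_obs = u_of(x, y)
    n12 = n1 * (len(combined) - n1)
    lo = min(u_obs, n12 - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        ui = u_of(xs, ys)
        total += 1
        if min(ui, n12 - ui) <= lo + 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_small_example_exact(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5), rng.integers(2, 6)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        u, p = mann_whitney(x, y)
        u_ref, p_ref = brute_force_mw_p(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_exact_agrees_with_scipy_8v8(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1.0, 1, size=8)
        # n1+n2 = 16 > 12: our normal approximation vs scipy's exact p
        u, p = mann_whitney(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=0.02)

    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=5),
        st.lists(st.integers(0, 30), min_size=2, max_size=5),
    )
    @settings(max_examples=30, deadline=None)
    def test_property_matches_scipy_exact_untied(self, x, y):
        if len(set(x + y)) < len(x + y):
            return  # ties: exact enumeration path not exercised
        u, p = mann_whitney(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)


class TestTwoStage:
    def test_step_profile_change_point(self):
        rng = np.random.default_rng(1)
        tr = synthetic_step_trace(1.0, 3.0, 35, 25, 0.2, rng)
        split = split_two_stage(tr, noise_scale=0.2)
        assert abs(split.change_frame - 35) <= 1
        assert split.step_significant
        assert split.low_duration_s + split.high_duration_s == pytest.approx(tr.lifetime_s)

    def test_flat_profile_not_significant(self):
        rng = np.random.default_rng(2)
        tr = synthetic_step_trace(2.0, 2.0, 30, 30, 0.1, rng)
        split = split_two_stage(tr, noise_scale=0.5)
        assert not split.step_significant

    def test_monotone_ramp_splits_near_midpoint(self):
        profile = np.linspace(0, 1, 60)
        tr = Trace(rows=np.array([0]), t_start=0, t_end=59, frame_interval_s=1.0,
                   censored_start=False, censored_end=False,
                   intensity_profile=profile, peak=1.0)
        split = split_two_stage(tr)
        assert abs(split.change_frame - 30) <= 1

    def test_too_short_rejected(self):
        tr = synthetic_step_trace(1, 2, 3, 2, 0, np.random.default_rng(0))
        with pytest.raises(ConfigError):
            split_two_stage(tr)

    def test_noiseless_matches_exhaustive_oracle(self):
        """Argmin-RSS equals independent exhaustive search maximising the
        between-segment sum of squares."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            profile = rng.uniform(0, 5, size=rng.integers(6, 40))
            tr = Trace(rows=np.array([0]), t_start=0, t_end=len(profile) - 1,
                       frame_interval_s=1.0, censored_start=False, censored_end=False,
                       intensity_profile=profile, peak=float(profile.max()))
            split = split_two_stage(tr)
            n = len(profile)
            best_k, best_ss = None, -np.inf
            grand = profile.mean()
            for k in range(1, n):
                ss = k * (profile[:k].mean() - grand) ** 2 + (n - k) * (profile[k:].mean() - grand) ** 2
                if ss > best_ss + 1e-12:
                    best_k, best_ss = k, ss
            assert split.change_frame == best_k


def _trace(row, t0, t1):
    return Trace(rows=np.array([row]), t_start=t0, t_end=t1, frame_interval_s=1.0,
                 censored_start=False, censored_end=False,
                 intensity_profile=np.ones(t1 - t0 + 1), peak=1.0)


class TestAlign:
    def test_self_alignment_full(self):
        a = [_trace(3, 5, 20), _trace(8, 40, 60)]
        flags, frac = align_traces(a, a, n_rows_total=20)
        assert frac == 1.0 and all(flags)

    def test_empty_b_gives_zero(self):
        a = [_trace(3, 5, 20)]
        flags, frac = align_traces(a, [], n_rows_total=20)
        assert frac == 0.0

    def test_row_tolerance_respected(self):
        a = [_trace(3, 5, 20)]
        b_near = [_trace(4, 7, 22)]
        b_far = [_trace(9, 7, 22)]
        assert align_traces(a, b_near, 20, row_tol=1)[1] == 1.0
        assert align_traces(a, b_far, 20, row_tol=1)[1] == 0.0

    def test_one_to_one_assignment(self):
        a = [_trace(3, 5, 20), _trace(3, 6, 21)]
        b = [_trace(3, 5, 20)]
        flags, frac = align_traces(a, b, 20)
        assert sum(flags) == 1 and frac == 0.5
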