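"""Endpoint detection, phase classification and replicate statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from ocmkit import (
    AreaProfile,
    CensoredEndpointError,
    CompressionCycleSpec,
    DisintegrationScenario,
    InsufficientDataError,
    InvalidInputError,
    aggregate_replicates,
    build_profile,
    classify_phases,
    detect_endpoint,
    percent_change,
    render_frames,
    sample_profile,
    smooth_profile,
)


def piecewise_profile(a0=95.0, peak=150.0, t_peak=40.0, t_d=112.0,
                      t_end=130.0, step=2.0, a_end=None):
    """Sampled triangular profile: a0 -> peak at t_peak -> a0 at t_d -> tail."""
    t = np.arange(0.0, t_end + step / 2, step)
    if a_end is None:
        a_end = a0 * 0.4
    xs = [0.0, t_peak, t_d, t_end]
    ys = [a0, peak, a0, a_end]
    return AreaProfile(times_s=t, areas_mm2=np.interp(t, xs, ys))


def oracle_crossing(profile):
    """Independent root-finder oracle for the baseline-return endpoint.

    Brackets the first post-peak baseline crossing of the linearly
    interpolated profile and solves it with Brent's method.
    """
    t, a = profile.times_s, profile.areas_mm2
    base = profile.baseline_mm2
    ipk = int(np.argmax(a))
    for i in range(ipk + 1, len(a)):
        if a[i] <= base:
            if a[i] == base:
                return float(t[i])
            f = lambda x: np.interp(x, t, a) - base
            return brentq(f, t[i - 1], t[i], xtol=1e-12)
    return None


class TestDetectEndpoint:
    def test_triangular_profile_crosses_at_112s(self):
        """Rise 95->150 by 40 s, linear fall back to 95 at 112 s."""
        res = detect_endpoint(piecewise_profile())
        assert not res.censored
        assert res.peak_s == pytest.approx(40.0)
        assert res.endpoint_s == pytest.approx(112.0, abs=1e-9)

    def test_constant_profile_degenerate_rule(self):
        prof = AreaProfile(times_s=np.arange(0, 10, 2.0),
                           areas_mm2=np.full(5, 95.0))
        res = detect_endpoint(prof)
        assert res.peak_s == 0.0
        assert res.endpoint_s == 2.0
        assert not res.censored

    def test_record_ending_above_baseline_is_censored(self):
        prof = AreaProfile(times_s=np.arange(0, 20, 2.0),
                           areas_mm2=np.linspace(95, 200, 10))
        res = detect_endpoint(prof)
        assert res.censored and res.endpoint_s is None

    def test_off_grid_crossing_matches_root_finder_oracle(self):
        """Interpolation endpoint equals an independent Brent solve."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            a0 = rng.uniform(50, 120)
            prof = piecewise_profile(
                a0=a0,
                peak=a0 * rng.uniform(1.5, 4.0),
                t_peak=rng.uniform(10, 40),
                t_d=rng.uniform(60, 110),
                t_end=125.0,
                a_end=a0 * rng.uniform(0.1, 0.6),
            )
            res = detect_endpoint(prof)
            assert res.endpoint_s == pytest.approx(oracle_crossing(prof),
                                                   abs=1e-9)


class TestClassifyPhases:
    def test_three_phase_partition_of_the_record(self):
        prof = piecewise_profile()
        ph = classify_phases(prof, detect_endpoint(prof))
        assert ph.swelling == (0.0, 40.0)
        assert ph.initial_washaway == (40.0, pytest.approx(112.0))
        assert ph.final_washaway == (pytest.approx(112.0), 130.0)
        assert ph.low_confidence_tail

    def test_no_swelling_gives_zero_width_phase(self):
        prof = AreaProfile(times_s=np.arange(0, 10, 2.0),
                           areas_mm2=np.array([95, 90, 80, 70, 60.0]))
        ph = classify_phases(prof, detect_endpoint(prof))
        assert ph.swelling == (0.0, 0.0)

    def test_record_ending_at_endpoint_has_empty_tail(self):
        t = np.arange(0.0, 112.1, 2.0)
        prof = AreaProfile(times_s=t,
                           areas_mm2=np.interp(t, [0, 40, 112], [95, 150, 95]))
        ph = classify_phases(prof, detect_endpoint(prof))
        assert ph.final_washaway[0] == pytest.approx(ph.final_washaway[1])

    def test_censored_input_rejected(self):
        prof = AreaProfile(times_s=np.arange(0, 20, 2.0),
                           areas_mm2=np.linspace(95, 200, 10))
        with pytest.raises(CensoredEndpointError):
            classify_phases(prof, detect_endpoint(prof))


class TestAggregateReplicates:
    def test_closed_form_mean_and_sd(self):
        s = aggregate_replicates([100.0, 110.0, 120.0], "1.9")
        assert (s.n, s.mean_s) == (3, 110.0)
        assert s.sd_s == pytest.approx(10.0)

    def test_single_replicate_reports_zero_sd(self):
        s = aggregate_replicates([112.0])
        assert (s.n, s.mean_s, s.sd_s) == (1, 112.0, 0.0)

    def test_empty_and_censored_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_replicates([])
        with pytest.raises(InvalidInputError):
            aggregate_replicates([100.0, None, 120.0])
        with pytest.raises(InvalidInputError):
            aggregate_replicates([100.0, float("nan")])

    @given(st.lists(st.floats(1, 1e4), min_size=2, max_size=20))
    def test_matches_direct_recomputation(self, xs):
        s = aggregate_replicates(xs)
        mean = sum(xs) / len(xs)
        sd = (sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5
        assert s.mean_s == pytest.approx(mean, rel=1e-9)
        assert s.sd_s == pytest.approx(sd, rel=1e-9, abs=1e-9)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, new, expected",
        [(112, 153, 36.6), (11, 34, 209.1), (112, 112, 0.0)],
    )
    def test_reported_to_one_decimal(self, ref, new, expected):
        assert percent_change(ref, new) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_change(0, 100)


class TestBuildProfile:
    def test_samples_once_per_cycle(self):
        scn = DisintegrationScenario(T_d_s=8.0, t_peak_s=3.0, t_end_s=11.4,
                                     per_cycle_noise_cv=0.0, lag_s=1.34)
        stack, _ = render_frames(scn)
        prof = build_profile(stack)
        assert np.allclose(prof.times_s, [1.34, 3.34, 5.34, 7.34, 9.34, 11.34])
        assert prof.baseline_mm2 == prof.areas_mm2[0]

    def test_areas_track_generator_truth(self):
        scn = DisintegrationScenario(T_d_s=20.0, per_cycle_noise_cv=0.02,
                                     seed=11)
        stack, manifest = render_frames(scn)
        prof = build_profile(stack)
        truth = np.asarray(manifest["true_areas_mm2"])
        assert np.max(np.abs(prof.areas_mm2 - truth) / truth) < 0.05

    def test_single_frame_stack_rejected(self):
        scn = DisintegrationScenario(T_d_s=20.0)
        stack, _ = render_frames(scn)
        stack.frames = stack.frames[:1]
        stack.timestamps_ms = stack.timestamps_ms[:1]
        with pytest.raises(InsufficientDataError):
            build_profile(stack)


class TestSmoothing:
    def test_moving_median_suppresses_single_spike(self):
        t = np.arange(0, 20, 2.0)
        a = np.full(10, 50.0)
        a[5] = 200.0
        sm = smooth_profile(AreaProfile(times_s=t, areas_mm2=a))
        assert sm.areas_mm2[5] == 50.0

    def test_even_window_rejected(self):
        prof = piecewise_profile()
        with pytest.raises(InvalidInputError):
            smooth_profile(prof, window=4)


def test_profile_validation():
    with pytest.raises(InsufficientDataError):
        AreaProfile(times_s=np.array([0.0]), areas_mm2=np.array([1.0]))
    with pytest.raises(InvalidInputError):
        AreaProfile(times_s=np.array([0.0, 0.0]), areas_mm2=np.array([1.0, 1.0]))
    with pytest.raises(InvalidInputError):
        AreaProfile(times_s=np.array([0.0, 1.0]), areas_mm2=np.array([1.0, -1.0]))


def test_endpoint_nonincreasing_in_erosion_rate():
    """Faster wash-away (steeper decline) never delays the endpoint."""
    a0, s, t_peak = 95.0, 4.0, 10.0
    rates = np.linspace(0.5, 12.0, 20)  # mm^2/s of area loss after the peak
    endpoints = []
    for rate in rates:
        t_d = t_peak + (s - 1) * a0 / rate
        scn = DisintegrationScenario(
            T_d_s=t_d, A0_mm2=a0, swell_ratio=s, t_peak_s=t_peak,
            t_end_s=t_d + (1 - 0.2) * a0 / rate,  # tail continues at same rate
            per_cycle_noise_cv=0.0,
        )
        prof, _ = sample_profile(scn)
        endpoints.append(detect_endpoint(prof).endpoint_s)
    assert all(e1 >= e2 for e1, e2 in zip(endpoints, endpoints[1:]))
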