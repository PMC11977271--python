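"""Inverse computations: the 5% rule, events, velocimetry, interfaces, diagnosis."""

import numpy as np
import pytest

from discsense.detection import (
    PROTOCOLS,
    classify_deformability,
    detect_events,
    estimate_velocity,
    locate_interface,
    sensor_state,
    sensor_state_series,
)
from discsense.optics import (
    ChannelGeometry,
    LdrModel,
    LedSource,
    OpticalMedium,
    SensorTrace,
    li_signal,
)
from discsense import synthetic

from conftest import constant_velocity_positions


class TestSensorState:
    def test_at_baseline_enabled(self):
        assert sensor_state(0.9, 0.9) == "enabled"

    def test_plasma_vs_rbc_contrast_disables(self):
        # the printed plasma (0.90) vs RBC (0.72) levels: deficit 0.18 >= 5%
        assert sensor_state(0.72, 0.90) == "disabled"

    def test_just_below_threshold_enabled(self):
        assert sensor_state(0.851, 0.9) == "enabled"  # deficit 0.049

    def test_hysteresis_half_threshold(self):
        assert sensor_state(0.86, 0.9, previous="disabled") == "disabled"  # 0.04 >= 0.025
        assert sensor_state(0.88, 0.9, previous="disabled") == "enabled"  # 0.02 < 0.025
        assert sensor_state(0.86, 0.9, previous="enabled") == "enabled"

    def test_series_carries_state(self):
        li = np.array([0.9, 0.84, 0.87, 0.89, 0.84])
        states = sensor_state_series(li, 0.9)
        assert list(states) == ["enabled", "disabled", "disabled", "enabled", "disabled"]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            sensor_state(0.9, 0.9, threshold=0.0)


def _pass_trace(v_mm_s, n_droplets=1, spacing_mm=6.0, noise=0.0, seed=0, sample_rate=200.0):
    """Constant-velocity droplet pass(es) rendered through the forward optics."""
    array = synthetic.default_array(first_center=15.0)
    led, ldr = LedSource(3.5), LdrModel()
    oil = OpticalMedium("blue oil", 0.1265)
    water = OpticalMedium("water", 0.0)
    span_mm = 4.0 + array.positions[-1] - array.positions[0] + spacing_mm * (n_droplets - 1) + 4.0
    t = np.arange(0.0, span_mm / v_mm_s, 1.0 / sample_rate)
    x0 = array.positions[0] - 4.0
    pos = constant_velocity_positions(t, v_mm_s, x0)
    extra = [
        (pos - spacing_mm * (k + 1), 1.0, water) for k in range(n_droplets - 1)
    ]
    trace = li_signal(t, pos, 1.0, water, array, led, ldr, oil, channel_depth=2.0,
                      extra_shadows=extra)
    if noise > 0:
        rng = np.random.default_rng(seed)
        trace.li = np.clip(trace.li + rng.normal(0, noise, trace.li.shape), 0, 1)
    return trace, array


class TestDetectEvents:
    def test_flat_trace_no_events(self):
        t = np.arange(0, 10, 0.01)
        trace = SensorTrace(time=t, li=np.full((t.size, 3), 0.8))
        events = detect_events(trace)
        assert [len(e) for e in events] == [0, 0, 0]

    def test_single_pass_three_ordered_peaks(self):
        trace, _ = _pass_trace(2.0)
        events = detect_events(trace, baseline="global")
        assert [len(e) for e in events] == [1, 1, 1]
        times = [e[0].time for e in events]
        assert times[0] < times[1] < times[2]
        assert all(e[0].polarity == "peak" for e in events)

    def test_two_droplets_two_events_per_sensor(self):
        trace, _ = _pass_trace(2.0, n_droplets=2)
        events = detect_events(trace, baseline="global")
        assert [len(e) for e in events] == [2, 2, 2]

    def test_trough_polarity_for_dyed_droplet(self):
        # reversed contrast: dyed droplet in transparent oil blocks the light
        array = synthetic.default_array()
        t = np.arange(0, 8, 0.005)
        pos = constant_velocity_positions(t, 2.0, array.positions[0] - 4.0)
        trace = li_signal(t, pos, 1.0, OpticalMedium("dyed", 2.0), array,
                          LedSource(3.5), LdrModel(), OpticalMedium("clear oil", 0.0))
        events = detect_events(trace, baseline="global")
        assert [len(e) for e in events] == [1, 1, 1]
        assert all(e[0].polarity == "trough" for e in events)

    def test_threshold_monotone_event_count(self):
        trace, _ = _pass_trace(2.0, noise=0.005, seed=3)
        counts = []
        for thr in (0.02, 0.05, 0.1, 0.2, 0.5):
            events = detect_events(trace, threshold=thr, baseline="global")
            counts.append(sum(len(e) for e in events))
        assert np.all(np.diff(counts) <= 0)

    def test_short_trace_rejected(self):
        t = np.arange(0, 0.5, 0.01)
        trace = SensorTrace(time=t, li=np.full((t.size, 1), 0.5))
        with pytest.raises(ValueError):
            detect_events(trace, baseline="rolling", baseline_window_s=2.0)


class TestEstimateVelocity:
    def test_printed_interval_examples(self):
        # 1.3 mm pitch in 0.1 s -> 13 mm/s; in 1.3 s -> 1 mm/s
        est = estimate_velocity([[1.0], [1.1], [1.2]], pitch=1.3)
        assert est.mean_mm_s == pytest.approx(13.0)
        est = estimate_velocity([[0.0], [1.3]], pitch=1.3)
        assert est.mean_mm_s == pytest.approx(1.0)

    def test_constant_velocity_recovered_exactly(self):
        trace, array = _pass_trace(2.0)
        events = detect_events(trace, baseline="global")
        est = estimate_velocity(events, pitch=array.pitch)
        assert est.mean_mm_s == pytest.approx(2.0, rel=0.005)

    def test_unmatched_events_reported(self):
        est = estimate_velocity([[1.0, 2.0], [1.1]], pitch=1.3)
        assert est.n_unmatched == 1
        assert len(est.per_pair) == 1

    def test_needs_two_sensors(self):
        with pytest.raises(ValueError):
            estimate_velocity([[1.0], []], pitch=1.3)

    def test_simultaneous_event_skipped_never_zero_interval(self):
        # a same-time event on the outer sensor cannot be the match; the
        # greedy matcher takes the next later one, so dt is always > 0
        est = estimate_velocity([[1.0], [1.0, 2.0]], pitch=1.3)
        assert est.per_pair[0][1] == pytest.approx(1.0)
        assert est.n_unmatched == 1


class TestLocateInterface:
    def test_full_transparent_channel_reads_capacity(self, channel):
        est = locate_interface(["enabled"] * 3, [15.0, 16.3, 17.6], ChannelGeometry(40.0, 1.0, 2.0))
        assert est.volume_estimate_ul == pytest.approx(80.0)
        assert est.lower_bound == 0.0
        assert est.upper_bound == pytest.approx(14.5)

    def test_bracket_between_last_disabled_and_first_enabled(self, channel):
        est = locate_interface(["disabled", "disabled", "enabled"], [15.0, 16.3, 17.6], channel)
        assert est.lower_bound == pytest.approx(16.3)
        assert est.upper_bound == pytest.approx(17.6)

    def test_all_disabled(self, channel):
        est = locate_interface(["disabled"] * 3, [15.0, 16.3, 17.6], channel)
        assert est.upper_bound == channel.length_d0_mm
        assert est.lower_bound == pytest.approx(18.1)

    def test_bracket_contains_true_interface(self, channel):
        # simulate a boundary at x_b: sensors inward of it shadowed
        positions = np.array([15.0, 16.3, 17.6])
        for x_b in (14.0, 15.5, 17.0, 20.0):
            states = ["enabled" if p > x_b else "disabled" for p in positions]
            est = locate_interface(states, positions, channel)
            assert est.lower_bound <= x_b or x_b < positions[0]
            assert x_b <= est.upper_bound or x_b > positions[-1]

    def test_non_monotone_warns_widest_bracket(self, channel):
        with pytest.warns(UserWarning):
            est = locate_interface(["enabled", "disabled", "enabled"], [15.0, 16.3, 17.6], channel)
        assert est.lower_bound == pytest.approx(15.0)
        assert est.upper_bound == pytest.approx(16.3)


class TestClassifyDeformability:
    @pytest.mark.parametrize(
        "label,expected",
        [("normal", "normal"), ("GA_0.01", "GA_0.01"),
         ("GA_0.02", "GA_0.02"), ("patient", "patient-like")],
    )
    def test_four_class_round_trip(self, label, expected):
        trace, _ = synthetic.make_sedimentation(label, noise_sigma=0.005, seed=11)
        call = classify_deformability(trace, protocol="four_class")
        assert call.label == expected

    def test_si_estimate_brackets_truth(self):
        trace, truth = synthetic.make_sedimentation("GA_0.01", noise_sigma=0.0, seed=0)
        call = classify_deformability(trace, protocol="four_class")
        assert call.si_estimate == pytest.approx(truth["si_infinity"], abs=0.05)

    def test_fig4_counts_and_labels(self):
        proto = PROTOCOLS["fig4"]
        expected = {"normal": 2, "GA_0.01": 1, "GA_0.02": 0}
        for label, count in expected.items():
            trace, _ = synthetic.make_sedimentation(
                label, array_positions_from_outer=proto.positions_from_outer, seed=5
            )
            call = classify_deformability(trace, protocol="fig4")
            assert call.count_at_read == count
            assert call.label == label

    def test_unmapped_count_is_indeterminate(self):
        trace, _ = synthetic.make_sedimentation("normal", seed=1)
        call = classify_deformability(trace, protocol="four_class", calibration={0: "GA_0.02"})
        assert call.label == "indeterminate"

    def test_read_time_outside_trace_rejected(self):
        trace, _ = synthetic.make_sedimentation("normal", seed=1, t_end=100.0)
        with pytest.raises(ValueError):
            classify_deformability(trace, protocol="four_class")

    def test_enabled_counts_threshold_monotone(self):
        from dataclasses import replace

        trace, _ = synthetic.make_sedimentation("GA_0.01", noise_sigma=0.005, seed=9)
        counts = []
        for thr in (0.05, 0.1, 0.2):
            call = classify_deformability(trace, protocol=replace(PROTOCOLS["four_class"], threshold=thr))
            counts.append(call.count_at_read)
        assert np.all(np.diff(counts) >= 0)  # raising threshold never disables more
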