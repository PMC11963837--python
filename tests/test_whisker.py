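import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fapa import synthetic, whisker
from fapa.whisker import (
    NO_CHANGE,
    MovementCycle,
    TrackingFailureError,
    WhiskerTrace,
    build_trace,
    classify_amplitudes,
    clean_mask,
    cycle_auc,
    detect_change_point,
    detect_cycles,
    movement_spectrogram,
    segment_marker,
    whisker_angle,
)


def exhaustive_changepoint(x, penalty):
    """Independent oracle: brute-force search over every split index."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def cost(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    total = cost(x)
    best_k, best_gain = NO_CHANGE, -np.inf
    for k in range(1, n):
        gain = total - (cost(x[:k]) + cost(x[k:]))
        if gain > best_gain:
            best_gain, best_k = gain, k
    return best_k if best_gain > penalty else NO_CHANGE


class TestSegmentMarker:
    def test_exact_color_blob(self):
        frame = np.zeros((10, 10, 3))
        frame[2:4, 3:8] = [0.8, 0.2, 0.1]  # 10 pixels
        mask = segment_marker(frame, (0.8, 0.2, 0.1), tolerance=0.0)
        assert mask.sum() == 10

    def test_black_frame_red_reference_empty(self):
        mask = segment_marker(np.zeros((5, 5, 3)), (1.0, 0.0, 0.0), tolerance=10 / 255)
        assert not mask.any()

    def test_within_tolerance_blob_all_true(self):
        # oracle: brute-force per-pixel Chebyshev distance check
        rng = np.random.default_rng(0)
        ref = np.array([0.5, 0.4, 0.3])
        frame = np.zeros((12, 12, 3))
        blob = (slice(4, 8), slice(4, 8))
        frame[blob] = ref + rng.uniform(-5 / 255, 5 / 255, size=(4, 4, 3))
        mask = segment_marker(frame, ref, tolerance=5 / 255)
        expected = np.abs(frame - ref).max(axis=-1) <= 5 / 255
        np.testing.assert_array_equal(mask, expected)
        assert mask[blob].all()

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            segment_marker(np.zeros((2, 2)), (0, 0, 0), tolerance=-1)


class TestCleanMask:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True  # 100-px blob
        mask[10, 45] = True  # isolated, >20 px from the blob
        cleaned = clean_mask(mask, radius=5)
        assert cleaned[10:20, 10:20].all()
        assert not cleaned[10, 45]
        assert cleaned.sum() == 100

    def test_solid_disk_unchanged(self):
        yy, xx = np.ogrid[-15:16, -15:16]
        mask = (yy**2 + xx**2) <= 100
        np.testing.assert_array_equal(clean_mask(mask, radius=5), mask)

    def test_empty_mask_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            cleaned = clean_mask(np.zeros((5, 5), dtype=bool), radius=5)
        assert not cleaned.any()

    def test_nearby_satellite_kept(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:15, 10:15] = True
        mask[16, 16] = True  # within 5 px of the blob
        assert clean_mask(mask, radius=5).sum() == 26


class TestWhiskerAngle:
    def test_centroid_right_of_insertion_is_zero(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 15] = True
        assert whisker_angle(mask, (10, 10)) == pytest.approx(0.0)

    def test_centroid_above_insertion_is_90(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[5, 10] = True
        assert whisker_angle(mask, (10, 10)) == pytest.approx(90.0)

    def test_diagonal_is_45(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, 20] = True  # insertion + (drow=-10, dcol=+10)
        assert whisker_angle(mask, (20, 10)) == pytest.approx(45.0, abs=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(whisker.MissingMarkerError):
            whisker_angle(np.zeros((5, 5), dtype=bool), (2, 2))


class TestBuildTrace:
    def test_rebasing_subtracts_session_minimum(self):
        frames, insertion = synthetic.render_whisker_frames([12, 17, 10, 22])
        trace = build_trace(frames, color_ref=(1, 1, 1), tolerance=0.1,
                            insertion=insertion, fps=120.0)
        assert trace.rebased
        assert trace.angles.min() == 0.0
        np.testing.assert_allclose(trace.angles, [2, 7, 0, 12], atol=2.0)

    def test_constant_position_gives_zero_trace(self):
        frames, insertion = synthetic.render_whisker_frames([20] * 5)
        trace = build_trace(frames, (1, 1, 1), 0.1, insertion, fps=120.0)
        np.testing.assert_allclose(trace.angles, 0.0)

    def test_sinusoid_amplitude_recovered_from_generator(self):
        params = synthetic.WhiskerSimParams(frequency_hz=4, amplitude_deg=30,
                                            fps=120, duration_s=2)
        trace, _ = synthetic.simulate_whisker_trace(params)
        assert trace.angles.max() == pytest.approx(30.0, abs=0.5)

    def test_missing_marker_interpolated(self):
        frames, insertion = synthetic.render_whisker_frames([10, 20, 30, 40])
        frames[1] = 0.0  # marker absent for one frame
        trace = build_trace(frames, (1, 1, 1), 0.1, insertion, fps=120.0)
        # interpolated between neighbors: rebased ~ [0, 10, 20, 30]
        np.testing.assert_allclose(np.diff(trace.angles), 10.0, atol=2.5)

    def test_majority_missing_fails(self):
        frames, insertion = synthetic.render_whisker_frames([10, 20, 30, 40])
        frames[1:] = 0.0
        with pytest.raises(TrackingFailureError):
            build_trace(frames, (1, 1, 1), 0.1, insertion, fps=120.0)


class TestChangePoint:
    def test_step_found_at_50(self):
        x = np.concatenate([np.zeros(50), np.full(50, 20.0)])
        assert detect_change_point(x, penalty=1.0) == 50
        assert exhaustive_changepoint(x, 1.0) == 50

    def test_constant_trace_is_no_change(self):
        assert detect_change_point(np.full(20, 3.0)) == NO_CHANGE

    def test_larger_of_two_steps_wins(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0), np.full(50, 30.0)])
        k = detect_change_point(x, penalty=1.0)
        assert k == exhaustive_changepoint(x, 1.0) == 100

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_change_point(np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        x = rng.normal(size=n)
        x[n // 2:] += rng.uniform(0, 3)
        penalty = float(rng.uniform(0, 2))
        assert detect_change_point(x, penalty=penalty) == exhaustive_changepoint(x, penalty)


class TestCycles:
    def test_single_triangle_cycle(self):
        x = np.array([5, 0, 12.5, 25, 12.5, 0, 5], dtype=float)
        cycles = detect_cycles(WhiskerTrace(angles=x, fps=10))
        assert len(cycles) == 1
        assert cycles[0].amplitude == pytest.approx(25.0)
        assert cycles[0].protraction_span == (1, 3)
        assert cycles[0].retraction_span == (3, 5)

    def test_flat_trace_has_no_cycles(self):
        assert detect_cycles(WhiskerTrace(angles=np.ones(20), fps=10)) == []

    def test_8hz_sinusoid_has_16ish_cycles(self):
        params = synthetic.WhiskerSimParams(frequency_hz=8, amplitude_deg=30,
                                            fps=120, duration_s=2)
        trace, _ = synthetic.simulate_whisker_trace(params)
        assert len(detect_cycles(trace)) == pytest.approx(16, abs=1)

    def test_cycles_tile_without_overlap(self):
        rng = np.random.default_rng(3)
        trace = WhiskerTrace(angles=rng.uniform(0, 10, 200), fps=100)
        cycles = detect_cycles(trace)
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert a.end_index == b.start_index
        assert all(c.amplitude >= 0 for c in cycles)

    def test_plateau_minimum_midpoint(self):
        x = np.array([5, 2, 2, 2, 5, 1, 5], dtype=float)
        cycles = detect_cycles(WhiskerTrace(angles=x, fps=10))
        assert cycles[0].start_index == 2  # midpoint of the 3-sample plateau


class TestClassifyAmplitudes:
    def _cycles(self, amps):
        return [MovementCycle(i, i, i, i + 1, a) for i, a in enumerate(amps)]

    def test_threshold_is_mean(self):
        out = classify_amplitudes(self._cycles([10, 20, 30]))
        assert out.threshold == pytest.approx(20.0)
        assert (out.long_count, out.short_count) == (1, 2)

    def test_ties_are_short(self):
        out = classify_amplitudes(self._cycles([7, 7, 7]))
        assert out.long_count == 0
        assert out.short_count == 3

    def test_symmetric_pair(self):
        out = classify_amplitudes(self._cycles([5, 35]))
        assert out.threshold == pytest.approx(20.0)
        assert (out.long_count, out.short_count) == (1, 1)
        assert sum(out.proportions) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_amplitudes([])


class TestCycleAuc:
    def test_flat_zero_cycle(self):
        trace = WhiskerTrace(angles=np.zeros(10), fps=10)
        assert cycle_auc(trace, MovementCycle(0, 0, 5, 9, 0.0)) == 0.0

    def test_triangle_area(self):
        # triangle 0 -> 20 -> 0 over 1 s: area = 1/2 * base * height = 10
        fps = 100
        up = np.linspace(0, 20, fps // 2 + 1)
        x = np.concatenate([up, up[-2::-1]])
        trace = WhiskerTrace(angles=x, fps=fps)
        auc = cycle_auc(trace, MovementCycle(0, 0, fps // 2, len(x) - 1, 20.0))
        assert auc == pytest.approx(10.0, rel=1e-3)

    def test_linearity_in_amplitude(self):
        fps = 100
        up = np.linspace(0, 20, 51)
        x = np.concatenate([up, up[-2::-1]])
        t1 = WhiskerTrace(angles=x, fps=fps)
        t2 = WhiskerTrace(angles=2 * x, fps=fps)
        cyc = MovementCycle(0, 0, 50, len(x) - 1, 20.0)
        assert cycle_auc(t2, cyc) == pytest.approx(2 * cycle_auc(t1, cyc))

    def test_rebased_trace_auc_nonnegative(self):
        rng = np.random.default_rng(1)
        trace = WhiskerTrace(angles=rng.uniform(0, 5, 100), fps=100).rebase()
        for cyc in detect_cycles(trace):
            assert cycle_auc(trace, cyc) >= 0


class TestSpectrogram:
    def test_8hz_peak_at_every_slice(self):
        params = synthetic.WhiskerSimParams(frequency_hz=8, amplitude_deg=30,
                                            fps=120, duration_s=4)
        trace, _ = synthetic.simulate_whisker_trace(params)
        _, freqs, power = movement_spectrogram(trace)
        peaks = freqs[np.argmax(power, axis=0)]
        assert np.abs(peaks - 8.0).max() <= 1.0

    def test_flat_trace_has_no_nonzero_frequency_power(self):
        trace = WhiskerTrace(angles=np.full(240, 2.0), fps=120)
        _, freqs, power = movement_spectrogram(trace)
        assert power[freqs > 0].max() < 1e-20

    def test_two_tone_peaks(self):
        t = np.arange(480) / 120
        x = np.sin(2 * np.pi * 3 * t) + np.sin(2 * np.pi * 15 * t)
        trace = WhiskerTrace(angles=x, fps=120).rebase()
        _, freqs, power = movement_spectrogram(trace)
        avg = power.mean(axis=1)
        low = freqs[freqs < 9][np.argmax(avg[freqs < 9])]
        high = freqs[freqs >= 9][np.argmax(avg[freqs >= 9])]
        assert low == pytest.approx(3, abs=1)
        assert high == pytest.approx(15, abs=1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            movement_spectrogram(WhiskerTrace(angles=np.zeros(10), fps=120))


class TestParameterRecovery:
    @pytest.mark.parametrize("freq", [2, 5, 8, 12])
    @pytest.mark.parametrize("amp", [10.0, 40.0])
    def test_frequency_and_amplitude_recovered(self, freq, amp):
        params = synthetic.WhiskerSimParams(
            frequency_hz=freq, amplitude_deg=amp, noise_sd_deg=amp / 10,
            fps=120, duration_s=8, seed=freq * 100 + int(amp),
        )
        trace, truth = synthetic.simulate_whisker_trace(params)
        _, freqs, power = movement_spectrogram(trace)
        dominant = freqs[np.argmax(power.mean(axis=1))]
        assert dominant == pytest.approx(freq, abs=1.0)
        cycles = detect_cycles(trace, smooth_s=0.3 / freq,
                               min_prominence=0.4 * amp)
        mean_amp = np.mean([c.amplitude for c in cycles])
        assert mean_amp == pytest.approx(amp, rel=0.10)


class TestParalysisPhenotype:
    def test_transection_schedule_collapses_cycle_auc(self):
        schedule = synthetic.make_schedule("transection", residual=0.02)
        aucs = []
        for session in (0, 5):
            mult = schedule.multipliers[session, 0]
            params = synthetic.WhiskerSimParams(
                frequency_hz=6, amplitude_deg=30, fps=120, duration_s=2,
                multiplier=mult, noise_sd_deg=0.05, seed=session,
            )
            trace, _ = synthetic.simulate_whisker_trace(params)
            cycles = detect_cycles(trace, smooth_s=0.04, min_prominence=0.1)
            aucs.append(np.mean([cycle_auc(trace, c) for c in cycles]) if cycles else 0.0)
        assert aucs[1] < 0.2 * aucs[0]


@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=50))
@settings(max_examples=50, deadline=None)
def test_rebased_minimum_is_exactly_zero(angles):
    trace = WhiskerTrace(angles=np.asarray(angles), fps=10.0).rebase()
    assert trace.angles.min() == 0.0
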