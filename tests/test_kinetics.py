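"""Front detection, distance–time traces, and sqrt-time kinetics."""

import numpy as np
import pytest

from colorkym import (
    FrameSequence,
    FrontTrace,
    LineSpec,
    ValidationError,
    annotate_front,
    average_speed,
    build_kymograph,
    detect_front_row,
    fit_sqrt_kinetics,
    trace_front,
)

BG = (235, 224, 200)
REACTED = (196, 80, 60)
CONTRAST = float(np.linalg.norm(np.array(BG, float) - np.array(REACTED, float)))


def step_row(length=100, last_reacted=56, reacted=REACTED, bg=BG):
    row = np.empty((length, 3), dtype=np.uint8)
    row[:] = bg
    row[: last_reacted + 1] = reacted
    return row


def make_trace(times, pos_mm, mm_per_px=1.0):
    pos = np.asarray(pos_mm, dtype=float)
    detected = ~np.isnan(pos)
    return FrontTrace(
        times=np.asarray(times, dtype=float),
        positions_px=pos / mm_per_px,
        positions_mm=pos,
        detected=detected,
        mm_per_px=mm_per_px,
    )


class TestDetectFrontRow:
    def test_uniform_background_has_no_front(self):
        row = np.full((50, 3), BG, dtype=np.uint8)
        assert detect_front_row(row, BG, threshold=30) is None

    def test_step_edge_located_at_half_contrast_midpoint(self):
        # reacted for 0..56, background from 57: half-contrast threshold
        # crosses the smoothed profile exactly at 56.5
        row = step_row(last_reacted=56)
        pos = detect_front_row(row, BG, threshold=CONTRAST / 2, direction="increasing")
        assert pos == pytest.approx(56.5, abs=1e-9)

    def test_oracle_crossing_interpolation(self):
        # brute-force oracle: smooth distances by hand, find last >= thr,
        # interpolate the crossing
        row = step_row(last_reacted=30)
        thr = 80.0
        d = np.linalg.norm(row.astype(float) - np.array(BG, float), axis=1)
        padded = np.pad(d, 1, mode="edge")
        s = np.convolve(padded, np.ones(3) / 3, mode="valid")
        i = np.nonzero(s >= thr)[0][-1]
        expected = i + (s[i] - thr) / (s[i] - s[i + 1])
        assert detect_front_row(row, BG, threshold=thr) == pytest.approx(expected)

    def test_decreasing_direction_mirrors(self):
        row = step_row(last_reacted=56)[::-1].copy()  # reacted on the right
        pos = detect_front_row(row, BG, threshold=CONTRAST / 2, direction="decreasing")
        assert pos == pytest.approx(len(row) - 1 - 56.5, abs=1e-9)

    def test_threshold_above_contrast_finds_nothing(self):
        assert detect_front_row(step_row(), BG, threshold=CONTRAST * 2) is None

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValidationError):
            detect_front_row(step_row(), BG, threshold=-1)
        with pytest.raises(ValidationError):
            detect_front_row(step_row(), BG, threshold=30, direction="sideways")
        with pytest.raises(ValidationError):
            detect_front_row(np.zeros((1, 3), dtype=np.uint8), BG, threshold=30)


def reacted_kymograph(fronts_px, length=120, bg=BG, reacted=REACTED):
    """Rows reacted up to floor(front); NaN front = all background."""
    rows = np.empty((len(fronts_px), length, 3), dtype=np.uint8)
    rows[:] = bg
    for i, f in enumerate(fronts_px):
        if not np.isnan(f):
            rows[i, : int(np.floor(f)) + 1] = reacted
    from colorkym.kymograph import Kymograph

    return Kymograph(
        rows=rows,
        line=LineSpec(0, 0, length - 1, 0),
        fps=30.0,
        row_times=np.arange(len(fronts_px)) / 30.0,
    )


class TestTraceFront:
    def test_programmed_sqrt_front_recovered_within_one_pixel(self):
        t = np.arange(300) / 30.0
        truth = 40.0 * np.sqrt(t)
        kym = reacted_kymograph(truth, length=140)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=0.05)
        assert trace.detected.all()
        assert np.abs(trace.positions_px - truth).max() <= 1.0

    def test_all_background_kymograph_has_no_detections(self):
        kym = reacted_kymograph([np.nan] * 20)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=1.0)
        assert trace.n_detected == 0

    def test_static_reacted_kymograph_constant_position(self):
        kym = reacted_kymograph([50.2] * 15)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=1.0)
        assert trace.detected.all()
        assert np.ptp(trace.positions_px) == 0

    def test_monotone_front_in_monotone_detection_out(self):
        truth = np.linspace(5, 110, 80)
        kym = reacted_kymograph(truth)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=1.0)
        assert (np.diff(trace.positions_px) >= -1.0).all()

    def test_background_estimated_from_preroll(self):
        kym = reacted_kymograph([np.nan] * 10 + list(np.linspace(3, 60, 20)))
        kym.row_times = np.arange(30) / 30.0 - 10 / 30.0  # first 10 rows pre-event
        trace = trace_front(kym, threshold=CONTRAST / 2, mm_per_px=1.0)
        assert trace.detected[10:].all()
        assert not trace.detected[:10].any()

    def test_no_preroll_and_no_background_rejected(self):
        kym = reacted_kymograph([10.0] * 5)
        with pytest.raises(ValidationError):
            trace_front(kym, threshold=30, mm_per_px=1.0)


class TestAverageSpeed:
    def test_paper_style_11mm_in_10s(self):
        trace = make_trace([0.0, 5.0, 10.0], [0.0, 11.0 / np.sqrt(2), 11.0])
        assert average_speed(trace, 0.0, 10.0) == pytest.approx(1.1)

    def test_constant_position_has_zero_speed(self):
        trace = make_trace([0, 1, 2], [4.0, 4.0, 4.0])
        assert average_speed(trace, 0, 2) == 0.0

    def test_sqrt_trace_closed_form_window(self):
        t = np.linspace(0, 5, 501)
        trace = make_trace(t, 2.0 * np.sqrt(t))
        assert average_speed(trace, 1.0, 4.0) == pytest.approx((4 - 2) / 3)

    def test_linear_trace_speed_equals_slope_exactly(self):
        t = np.arange(20) / 10.0
        trace = make_trace(t, 0.7 * t + 0.3)
        assert average_speed(trace, 0.15, 1.85) == pytest.approx(0.7)

    def test_times_outside_detected_range_rejected(self):
        trace = make_trace([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            average_speed(trace, 0.0, 2.0)
        with pytest.raises(ValidationError):
            average_speed(trace, 2.0, 1.0)


class TestSqrtFit:
    def test_noiseless_sqrt_recovers_k_exactly(self):
        t = np.linspace(0, 20, 601)
        trace = make_trace(t, 3.0 * np.sqrt(t))
        fit = fit_sqrt_kinetics(trace)
        assert fit.k == pytest.approx(3.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.t_onset == 0.0
        assert fit.n_points == 601

    def test_closed_form_least_squares_oracle(self):
        # independent oracle: k = sum(x*sqrt(t')) / sum(t')
        t = np.linspace(0.0, 8.0, 97)
        x = 2.4 * np.sqrt(t) + 0.05 * np.sin(t)
        trace = make_trace(t, x)
        expected = float(x @ np.sqrt(t) / t.sum())
        assert fit_sqrt_kinetics(trace).k == pytest.approx(expected)

    def test_constant_zero_trace_gives_zero_k(self):
        trace = make_trace([0, 1, 2, 3], [0.0, 0.0, 0.0, 0.0])
        assert fit_sqrt_kinetics(trace).k == 0.0

    def test_noisy_position_recovery_within_5_percent(self):
        rng = np.random.default_rng(618)
        k_true, mm_per_px = 3.5, 0.05
        t = np.arange(600) / 30.0
        pos_px = k_true / mm_per_px * np.sqrt(t) + rng.normal(0, 0.5, len(t))
        trace = make_trace(t, pos_px * mm_per_px, mm_per_px=mm_per_px)
        fit = fit_sqrt_kinetics(trace)
        assert abs(fit.k - k_true) / k_true <= 0.05

    def test_too_few_points_rejected(self):
        trace = make_trace([0.0, 1.0], [np.nan, 1.0])
        with pytest.raises(ValidationError):
            fit_sqrt_kinetics(trace)


class TestAnnotate:
    def test_undetected_trace_leaves_image_unchanged(self):
        kym = reacted_kymograph([np.nan] * 8)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=1.0)
        assert (annotate_front(kym, trace) == kym.rows).all()

    def test_highlight_lands_on_rounded_positions(self):
        fronts = np.linspace(10, 80, 25)
        kym = reacted_kymograph(fronts)
        trace = trace_front(kym, background=BG, threshold=CONTRAST / 2, mm_per_px=1.0)
        out = annotate_front(kym, trace, highlight=(255, 0, 255))
        marked = np.nonzero((out == (255, 0, 255)).all(axis=2))
        assert len(marked[0]) == trace.n_detected
        for row_i, col in zip(*marked):
            assert col == int(round(trace.positions_px[row_i]))

    def test_mismatched_trace_rejected(self):
        kym = reacted_kymograph([10.0] * 5)
        trace = make_trace([0, 1], [1.0, 2.0])
        with pytest.raises(ValidationError):
            annotate_front(kym, trace)


class TestEndToEnd:
    def test_synthetic_video_full_pipeline_speed(self):
        from colorkym import DiffusionScenario, make_diffusion_video

        sc = DiffusionScenario(duration=15.0, t0_offset=-2.0)
        seq, truth = make_diffusion_video(sc)
        kym = build_kymograph(
            seq, LineSpec(0, sc.width_px // 2, sc.length_px - 1, sc.width_px // 2)
        )
        trace = trace_front(kym, threshold=CONTRAST / 2, mm_per_px=sc.mm_per_px)
        v = average_speed(trace, 0.0, 10.0)
        assert v == pytest.approx(1.1, rel=0.02)
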