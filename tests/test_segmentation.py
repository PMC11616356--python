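"""Changepoint segmentation, classification, run/pause extraction."""
import numpy as np
import pandas as pd
import pytest

from beadmotility import (
    SegmentationConfig,
    Trace,
    TraceError,
    classify_segments,
    extract_runs_and_pauses,
    fit_segment,
    segment_record,
)


def piecewise_trace(pieces, rate=30.0, noise_sd=0.0, seed=0):
    """pieces: [(duration_s, velocity), ...] -> continuous Trace."""
    ts, xs = [], []
    t0, x0 = 0.0, 0.0
    for dur, v in pieces:
        t = np.arange(0, dur, 1 / rate)
        ts.append(t0 + t)
        xs.append(x0 + v * t)
        t0 += dur
        x0 += v * dur
    t = np.concatenate(ts)
    x = np.concatenate(xs)
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, len(x))
    return Trace(t=t, x=x, sample_rate=rate, meta={"record_id": "pw"})


class TestFitSegment:
    def test_exact_line(self):
        tr = piecewise_trace([(100.0, 0.17)])
        v, _b, resid = fit_segment(tr, 0.0, 100.0)
        assert v == pytest.approx(0.17, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_constant_trace_zero_slope(self):
        tr = piecewise_trace([(50.0, 0.0)])
        v, b, _ = fit_segment(tr, 0.0, 50.0)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_slope_within_ols_ci(self):
        # OLS sampling theory: slope SE = sigma * sqrt(12 / n) / T for a long run
        tr = piecewise_trace([(100.0, 0.17)], noise_sd=0.5, seed=1)
        v, _b, _r = fit_segment(tr, 0.0, 100.0)
        se = 0.5 * np.sqrt(12 / len(tr)) / 100.0
        assert abs(v - 0.17) < 4 * se

    def test_too_few_samples(self):
        tr = piecewise_trace([(10.0, 0.1)])
        with pytest.raises(TraceError):
            fit_segment(tr, 0.0, 0.05)


class TestSegmentRecordOracle:
    def test_noise_free_three_piece_recovery(self):
        tr = piecewise_trace([(100.0, 0.2), (100.0, 0.0), (100.0, -0.1)])
        seg = segment_record(tr, SegmentationConfig(n_replicates=1))
        assert len(seg) == 3
        assert np.allclose(seg["velocity"], [0.2, 0.0, -0.1], atol=1e-6)
        assert np.allclose(seg["t_start"], [0.0, 100.0, 200.0], atol=1.0)
        assert seg["retained"].all()

    def test_breakpoints_and_slopes_exact_for_long_pieces(self):
        pieces = [(60.0, 0.15), (40.0, -0.05), (80.0, 0.3), (30.0, 0.0)]
        tr = piecewise_trace(pieces)
        seg = segment_record(tr, SegmentationConfig(n_replicates=1))
        assert len(seg) == 4
        assert np.allclose(seg["velocity"], [v for _d, v in pieces], rtol=1e-6, atol=1e-9)
        starts = np.cumsum([0.0] + [d for d, _v in pieces[:-1]])
        assert np.allclose(seg["t_start"], starts, atol=1 / 30.0 + 1e-9)

    def test_segments_tile_record(self):
        tr = piecewise_trace([(50.0, 0.2), (30.0, 0.0)], noise_sd=0.5, seed=2)
        seg = segment_record(tr, SegmentationConfig(n_replicates=3))
        for _rep, sub in seg.groupby("replicate"):
            sub = sub.sort_values("t_start")
            assert sub.iloc[0]["t_start"] == pytest.approx(0.0)
            assert np.allclose(sub["t_end"].to_numpy()[:-1], sub["t_start"].to_numpy()[1:])
            total = sub["duration"].sum()
            assert total == pytest.approx(80.0, abs=1 / 30.0 + 1e-9)

    def test_replicates_have_distinct_penalties_but_same_tiling(self):
        tr = piecewise_trace([(60.0, 0.2), (60.0, 0.0)], noise_sd=0.5, seed=3)
        seg = segment_record(tr, SegmentationConfig(n_replicates=3))
        assert set(seg["replicate"]) == {0, 1, 2}

    def test_short_record_warns_empty(self):
        tr = piecewise_trace([(5.0, 0.1)])
        with pytest.warns(UserWarning, match="shorter than min_duration"):
            seg = segment_record(tr, SegmentationConfig())
        assert seg.empty

    def test_control_noise_trace_mostly_below_threshold(self):
        # pure-noise fixed-tether record: >= 90% of retained time below 0.085 nm/s
        rng = np.random.default_rng(4)
        t = np.arange(0, 600.0, 1 / 30.0)
        tr = Trace(t=t, x=rng.normal(0, 0.46, len(t)), sample_rate=30.0,
                   meta={"record_id": "ctrl"})
        seg = segment_record(tr, SegmentationConfig())
        ret = seg[seg["retained"]]
        frac = ret.loc[np.abs(ret["velocity"]) < 0.085, "duration"].sum() / ret["duration"].sum()
        assert frac >= 0.90


def seg_frame(rows):
    """rows: (t_start, t_end, velocity[, record, rep]) -> minimal segment table."""
    out = []
    for r in rows:
        t0, t1, v = r[:3]
        rec = r[3] if len(r) > 3 else "r0"
        rep = r[4] if len(r) > 4 else 0
        out.append(
            dict(record_id=rec, replicate=rep, t_start=t0, t_end=t1, duration=t1 - t0,
                 velocity=v, intercept=0.0, resid_sd=0.0, distance=v * (t1 - t0),
                 mean_force=np.nan, n_samples=int((t1 - t0) * 30), retained=(t1 - t0) >= 10)
        )
    return pd.DataFrame(out)


class TestClassification:
    def test_example_labels(self):
        seg = classify_segments(
            seg_frame([(0, 100, 0.2), (100, 200, -0.1), (200, 300, 0.05)])
        )
        assert list(seg["state"]) == ["moving", "moving", "paused"]
        assert list(seg["direction"]) == ["forward", "backward", "forward"]
        assert seg["v_rel"].iloc[0] == pytest.approx(0.2)

    def test_all_negative_record_reports_positive_forward(self):
        seg = classify_segments(seg_frame([(0, 100, -0.2), (100, 200, -0.15)]))
        assert (seg["direction"] == "forward").all()
        assert (seg["v_rel"] > 0).all()

    def test_threshold_boundary_is_moving(self):
        seg = classify_segments(seg_frame([(0, 100, 0.085), (100, 200, 0.2)]))
        assert seg["state"].iloc[0] == "moving"

    def test_global_sign_flip_invariance(self):
        base = seg_frame([(0, 100, 0.2), (100, 200, -0.1), (200, 300, 0.05)])
        flipped = base.copy()
        flipped["velocity"] *= -1
        flipped["distance"] *= -1
        a = classify_segments(base)
        b = classify_segments(flipped)
        assert list(a["direction"]) == list(b["direction"])
        assert np.allclose(a["v_rel"], b["v_rel"])

    def test_zero_net_tiebreak_warns(self):
        with pytest.warns(UserWarning, match="tie-break"):
            seg = classify_segments(seg_frame([(0, 100, 0.2), (100, 200, -0.2)]))
        assert seg["direction"].iloc[0] == "forward"


class TestRunsAndPauses:
    def test_consecutive_forward_segments_merge(self):
        seg = classify_segments(seg_frame([(0, 20, 0.1), (20, 30, 0.2)]))
        runs, pauses = extract_runs_and_pauses(seg)
        assert len(runs) == 1 and pauses.empty
        assert runs.iloc[0]["distance"] == pytest.approx(4.0)
        assert runs.iloc[0]["duration"] == pytest.approx(30.0)

    def test_pause_separates_runs(self):
        seg = classify_segments(
            seg_frame([(0, 30, 0.2), (30, 60, 0.01), (60, 90, 0.2)])
        )
        runs, pauses = extract_runs_and_pauses(seg)
        assert len(runs) == 2
        assert len(pauses) == 1
        assert pauses.iloc[0]["duration"] == pytest.approx(30.0)

    def test_direction_reversal_separates_runs(self):
        seg = classify_segments(seg_frame([(0, 30, 0.2), (30, 60, -0.15), (60, 90, 0.2)]))
        runs, _ = extract_runs_and_pauses(seg)
        assert len(runs) == 3
        assert list(runs["direction"]) == ["forward", "backward", "forward"]
        assert (runs["distance"] > 0).all()

    def test_flagged_segment_breaks_contiguity(self):
        seg = classify_segments(
            seg_frame([(0, 30, 0.2), (30, 38, 0.01), (38, 70, 0.2)])
        )
        runs, _ = extract_runs_and_pauses(seg)
        assert len(runs) == 2  # the 8 s flagged pause is not bridged

    def test_counts_conserved(self):
        seg = classify_segments(
            seg_frame([(0, 30, 0.2), (30, 60, 0.01), (60, 90, -0.2), (90, 120, 0.3)])
        )
        runs, pauses = extract_runs_and_pauses(seg)
        assert runs["n_segments"].sum() + pauses["n_segments"].sum() == seg["retained"].sum()
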