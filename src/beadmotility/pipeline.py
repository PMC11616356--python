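"""End-to-end analysis pipeline and its resolved configuration.

Stages: decimate -> EWMA smooth -> jump detection (full rate) ->
downsample -> drift correction -> jump-step subtraction -> changepoint
segmentation (n replicates) -> direction/pause classification -> run and
pause extraction -> distribution fits -> summary tables.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .driftcorr import DriftEstimate, combine_and_smooth, correct_drift, track_marker
from .kinetics import (
    WeightingRule,
    detect_jumps,
    fit_double_exponential_em,
    fit_exponential_weighted,
    fit_truncated_exponential,
    remove_jumps,
)
from .preprocess import decimate, downsample, ewma
from .segmentation import (
    SegmentationConfig,
    classify_segments,
    extract_runs_and_pauses,
    segment_record,
)
from .stats import summarize_dataset
from .trace import Trace

__all__ = ["PipelineConfig", "process_record", "analyze_dataset", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Fully resolved analysis parameters.

    Defaults are the study constants: decimation to 3 kHz, EWMA window of
    20 points, downsampling by 100, 10 s minimum segment duration,
    0.085 nm/s pause threshold, 10 s weighting basis and truncation point,
    1e-5 s EM tolerance, 3.5 pN force bins.
    """

    target_rate: float = 3000.0  # Hz
    ewma_window: int = 20  # points
    downsample_factor: int = 100
    min_duration: float = 10.0  # s
    pause_threshold: float = 0.085  # nm/s
    weight_basis: float = 10.0  # s
    t0: float = 10.0  # s, dwell-fit truncation
    em_tol: float = 1e-5  # s
    force_bin_width: float = 3.5  # pN
    bootstrap_B: int = 10000
    n_replicates: int = 3
    replicate_jitter: float = 0.25
    penalty: float | None = None
    penalty_scale: float = 2.5
    min_piece: float = 2.0  # s
    max_segment: float = 300.0  # s
    jump_min_amplitude: float = 5.0  # nm
    jump_max_transition: float = 0.01  # s
    drift_smooth_window: float = 20.0  # s
    drift_correction: bool = True
    velocity_fit_truncated: bool = True  # exclude pauses, truncate at threshold
    seed: int = 0

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            min_duration=self.min_duration,
            pause_threshold=self.pause_threshold,
            penalty=self.penalty,
            penalty_scale=self.penalty_scale,
            n_replicates=self.n_replicates,
            replicate_jitter=self.replicate_jitter,
            min_piece=self.min_piece,
            max_segment=self.max_segment,
            seed=self.seed,
        )

    def weighting_rule(self) -> WeightingRule:
        return WeightingRule(basis=self.weight_basis)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def drift_from_frames(
    frames: np.ndarray,
    rois: list,
    config: PipelineConfig,
    *,
    t_frames: np.ndarray | None = None,
    frame_rate: float = 1.0,
    nm_per_px: float = 50.0,
) -> DriftEstimate:
    """Track every fiducial ROI and combine into one drift estimate."""
    tracks = [
        track_marker(
            frames, roi, t_frames=t_frames, frame_rate=frame_rate, nm_per_px=nm_per_px
        )
        for roi in rois
    ]
    return combine_and_smooth(tracks, smooth_window=config.drift_smooth_window)


def process_record(
    trace: Trace,
    config: PipelineConfig | None = None,
    drift: DriftEstimate | None = None,
) -> dict:
    """Condition, drift-correct and segment one record.

    Returns a dict with the downsampled corrected trace, the detected jump
    events, and the classified segment table (all replicates).
    """
    config = config or PipelineConfig()
    full = trace
    if full.sample_rate > config.target_rate:
        full = decimate(full, config.target_rate)
    jumps = detect_jumps(
        full,
        min_amplitude=config.jump_min_amplitude,
        max_transition=config.jump_max_transition,
    )
    smoothed = ewma(full, config.ewma_window)
    low = downsample(smoothed, config.downsample_factor)
    if drift is not None and config.drift_correction:
        low = correct_drift(low, drift)
    if jumps:
        low = remove_jumps(low, jumps)
    segments = segment_record(low, config.segmentation_config())
    if not segments.empty:
        segments = classify_segments(segments, config.pause_threshold)
    return {"trace": low, "jumps": jumps, "segments": segments}


def analyze_dataset(
    records: list,
    config: PipelineConfig | None = None,
    drifts: dict | None = None,
) -> dict:
    """Run the full pipeline over a dataset of records and pool replicates.

    Parameters
    ----------
    records : list of Trace
    config : PipelineConfig
    drifts : dict, optional
        record_id -> DriftEstimate to subtract before segmentation.

    Returns
    -------
    dict with keys ``segments``, ``runs``, ``pauses``, ``jumps``, ``fits``,
    ``summary``.
    """
    config = config or PipelineConfig()
    drifts = drifts or {}
    seg_tables = []
    jumps = {}
    record_durations = {}
    for trace in records:
        res = process_record(trace, config, drift=drifts.get(trace.record_id))
        seg_tables.append(res["segments"])
        jumps[trace.record_id] = res["jumps"]
        record_durations[trace.record_id] = trace.duration + 1.0 / trace.sample_rate
    segments = pd.concat(
        [s for s in seg_tables if not s.empty], ignore_index=True
    ) if any(not s.empty for s in seg_tables) else pd.DataFrame()
    if segments.empty:
        warnings.warn("no segments produced by the pipeline", stacklevel=2)
        return {
            "segments": segments,
            "runs": pd.DataFrame(),
            "pauses": pd.DataFrame(),
            "jumps": jumps,
            "fits": {},
            "summary": {},
        }
    runs, pauses = extract_runs_and_pauses(segments)
    fits = fit_dataset(segments, runs, pauses, config)
    summary = summarize_dataset(segments, runs, pauses, record_durations)
    return {
        "segments": segments,
        "runs": runs,
        "pauses": pauses,
        "jumps": jumps,
        "fits": fits,
        "summary": summary,
    }


def fit_dataset(
    segments: pd.DataFrame,
    runs: pd.DataFrame,
    pauses: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Distribution fits for a pooled, classified segment table.

    Per-direction velocity PDFs are time-weighted exponential MLEs. By
    default they use moving segments only, left-truncated at the pause
    threshold (which recovers the underlying exponential mean by
    memorylessness); ``velocity_fit_truncated=False`` reproduces the plain
    [0, inf) fit over all direction-signed segments instead. Run distances
    get plain exponential fits; run and pause durations get truncated
    single-exponential and EM double-exponential fits.
    """
    rule = config.weighting_rule()
    ret = segments[segments["retained"]]
    n_rep = max(int(config.n_replicates), 1)
    fits = {}

    def _ci_count(durations):
        # replicate pooling duplicates records; weights duplicate velocities
        w = rule.weights(durations).astype(float)
        return (w.sum() ** 2 / np.sum(w * w)) / n_rep

    for direction in ("forward", "backward"):
        if config.velocity_fit_truncated:
            sel = ret[(ret["direction"] == direction) & (ret["state"] == "moving")]
            floor = config.pause_threshold
        else:
            sel = ret[ret["direction"] == direction]
            floor = 0.0
        if len(sel):
            durs = sel["duration"].to_numpy(dtype=float)
            fits[f"velocity_{direction}"] = fit_exponential_weighted(
                np.abs(sel["v_rel"].to_numpy(dtype=float)),
                durations=durs,
                rule=rule,
                floor=floor,
                independent_count=_ci_count(durs),
            )
    # control-style fit: all retained segments, |v|, domain [0, inf)
    all_durs = ret["duration"].to_numpy(dtype=float)
    fits["velocity_all"] = fit_exponential_weighted(
        np.abs(ret["velocity"].to_numpy(dtype=float)),
        durations=all_durs,
        rule=rule,
        independent_count=_ci_count(all_durs),
    )
    if runs is not None and len(runs):
        for direction in ("forward", "backward"):
            sub = runs[runs["direction"] == direction]
            if len(sub):
                fits[f"run_distance_{direction}"] = fit_exponential_weighted(
                    sub["distance"].to_numpy(dtype=float),
                    independent_count=len(sub) / n_rep,
                )
                durs = sub.loc[sub["duration"] >= config.t0, "duration"].to_numpy(dtype=float)
                if durs.size:
                    fits[f"run_duration_{direction}"] = fit_truncated_exponential(
                        durs, t0=config.t0, independent_count=durs.size / n_rep
                    )
                if durs.size >= 4:
                    fits[f"run_duration_{direction}_2exp"] = fit_double_exponential_em(
                        durs, t0=config.t0, tol=config.em_tol
                    )
    if pauses is not None and len(pauses):
        durs = pauses.loc[pauses["duration"] >= config.t0, "duration"].to_numpy(dtype=float)
        if durs.size:
            fits["pause_duration"] = fit_truncated_exponential(
                durs, t0=config.t0, independent_count=durs.size / n_rep
            )
        if durs.size >= 4:
            fits["pause_duration_2exp"] = fit_double_exponential_em(
                durs, t0=config.t0, tol=config.em_tol
            )
    return fits


def run_pipeline(inputs, config: PipelineConfig | None = None, outdir=None) -> dict:
    """File-level entry point: read traces, analyze, write artifacts.

    Parameters
    ----------
    inputs : list of Trace or paths to trace files
    config : PipelineConfig
    outdir : path, optional
        If given, writes segments.tsv, runs.tsv, pauses.tsv, fits.json,
        summary.json, config.json and a manifest.json listing every artifact.
    """
    config = config or PipelineConfig()
    records = [tr if isinstance(tr, Trace) else bio.read_trace(tr) for tr in inputs]
    if not records:
        raise ValueError("need at least one trace")
    results = analyze_dataset(records, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts = {}
        bio.write_segments(results["segments"], outdir / "segments.tsv")
        artifacts["segments"] = "segments.tsv"
        for name in ("runs", "pauses"):
            results[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            artifacts[name] = f"{name}.tsv"
        bio.write_fit(results["fits"], outdir / "fits.json")
        artifacts["fits"] = "fits.json"
        (outdir / "summary.json").write_text(
            json.dumps(results["summary"], indent=2, default=bio._json_default) + "\n"
        )
        artifacts["summary"] = "summary.json"
        (outdir / "config.json").write_text(config.to_json() + "\n")
        artifacts["config"] = "config.json"
        (outdir / "manifest.json").write_text(json.dumps(artifacts, indent=2) + "\n")
        results["outdir"] = outdir
    return results
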