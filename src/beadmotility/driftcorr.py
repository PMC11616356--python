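"""Fiducial-marker drift estimation and subtraction.

Surface-bound markers imaged at 0.5-1 Hz are tracked by normalized
cross-correlation of a reference ROI against each frame (parabolic sub-pixel
peak refinement); two or more marker trajectories are averaged, projected on
the motility axis, smoothed, and subtracted from the bead record.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .trace import Trace, TraceError

__all__ = [
    "MarkerTrack",
    "DriftEstimate",
    "TrackingError",
    "track_marker",
    "combine_and_smooth",
    "correct_drift",
    "qc_z_drift",
]


class TrackingError(RuntimeError):
    """Marker tracking failed (e.g. flat ROI with no structure)."""


@dataclass
class MarkerTrack:
    """Per-frame marker displacement relative to frame 0.

    ``xy`` is (n_frames, 2) displacement in nm, columns (x, y) with x along
    the image column axis (the motility axis). ``quality`` is the correlation
    peak height per frame, in [0, 1].
    """

    t_frames: np.ndarray
    xy: np.ndarray  # nm
    roi: tuple  # (r0, r1, c0, c1) pixels
    quality: np.ndarray
    nm_per_px: float = 1.0

    def __post_init__(self):
        self.t_frames = np.asarray(self.t_frames, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.quality = np.clip(np.asarray(self.quality, dtype=float), 0.0, 1.0)
        if len(self.xy) != len(self.t_frames) or len(self.quality) != len(self.t_frames):
            raise TraceError("MarkerTrack arrays must share one entry per frame")


@dataclass
class DriftEstimate:
    """Drift displacement along the motility axis; d(t0) = 0 by convention."""

    t: np.ndarray
    d: np.ndarray  # nm
    smoothing: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "d": self.d})


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Sub-pixel offset of a quadratic through three samples around a peak."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0 or abs(denom) < 1e-15:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def track_marker(
    frames: np.ndarray,
    roi: tuple,
    *,
    t_frames: np.ndarray | None = None,
    frame_rate: float = 1.0,
    nm_per_px: float = 1.0,
    search_pad: int = 8,
) -> MarkerTrack:
    """Track one fiducial marker by normalized cross-correlation.

    The reference ROI is cut from frame 0 and correlated against a padded
    search window in every frame; the correlation peak is refined to
    sub-pixel precision by parabolic interpolation, and its height is kept
    as a per-frame quality score.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise TrackingError("need a (n_frames, H, W) stack with >= 2 frames")
    r0, r1, c0, c1 = (int(v) for v in roi)
    H, W = frames.shape[1:]
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise TrackingError(f"ROI {roi} outside frame bounds {(H, W)}")
    ref = frames[0, r0:r1, c0:c1].astype(float)
    if ref.std() == 0:
        raise TrackingError("reference ROI has zero variance (flat image)")

    sr0, sr1 = max(0, r0 - search_pad), min(H, r1 + search_pad)
    sc0, sc1 = max(0, c0 - search_pad), min(W, c1 + search_pad)

    if t_frames is None:
        t_frames = np.arange(len(frames)) / frame_rate
    xy = np.zeros((len(frames), 2))
    quality = np.zeros(len(frames))
    for i, frame in enumerate(frames):
        win = frame[sr0:sr1, sc0:sc1].astype(float)
        if win.std() == 0:
            raise TrackingError(f"search window flat in frame {i}")
        cc = match_template(win, ref, pad_input=False)
        pr, pc = np.unravel_index(np.argmax(cc), cc.shape)
        dr = float(pr)
        dc = float(pc)
        if 0 < pr < cc.shape[0] - 1:
            dr += _parabolic_offset(cc[pr - 1, pc], cc[pr, pc], cc[pr + 1, pc])
        if 0 < pc < cc.shape[1] - 1:
            dc += _parabolic_offset(cc[pr, pc - 1], cc[pr, pc], cc[pr, pc + 1])
        # displacement of the marker relative to frame 0
        xy[i, 0] = (dc - (c0 - sc0)) * nm_per_px
        xy[i, 1] = (dr - (r0 - sr0)) * nm_per_px
        quality[i] = cc[pr, pc]
    xy -= xy[0]
    return MarkerTrack(
        t_frames=t_frames, xy=xy, roi=(r0, r1, c0, c1), quality=quality, nm_per_px=nm_per_px
    )


def combine_and_smooth(
    tracks: list,
    axis=(1.0, 0.0),
    smooth_window: float = 20.0,
) -> DriftEstimate:
    """Average marker tracks, project on the motility axis, and smooth.

    ``smooth_window`` is the moving-average span in seconds (centered,
    monotone-preserving for linear drift). A single track is accepted with a
    warning.
    """
    if len(tracks) == 0:
        raise TraceError("need at least one marker track")
    if len(tracks) == 1:
        warnings.warn("only one marker track supplied; averaging skipped", stacklevel=2)
    t0 = tracks[0].t_frames
    for tr in tracks[1:]:
        if len(tr.t_frames) != len(t0) or not np.allclose(tr.t_frames, t0):
            raise TraceError("marker tracks must share frame times")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = np.mean([tr.xy @ axis for tr in tracks], axis=0)

    if len(t0) > 1 and smooth_window > 0:
        dt = float(np.median(np.diff(t0)))
        w = max(1, int(round(smooth_window / dt)))
        w = min(w if w % 2 == 1 else w + 1, 2 * (len(proj) - 1) + 1)
        # pad by linear extrapolation so straight-line drift passes exactly
        half = w // 2
        if half > 0:
            left = 2 * proj[0] - proj[half:0:-1]
            right = 2 * proj[-1] - proj[-2 : -half - 2 : -1]
            padded = np.concatenate([left, proj, right])
            smoothed = np.convolve(padded, np.ones(w) / w, mode="valid")
        else:
            smoothed = proj.copy()
    else:
        w = 1
        smoothed = proj
    smoothed = smoothed - smoothed[0]
    return DriftEstimate(
        t=t0,
        d=smoothed,
        smoothing=f"moving_average:{w}frames(~{smooth_window:g}s)",
        meta={"n_markers": len(tracks)},
    )


def correct_drift(trace: Trace, drift: DriftEstimate) -> Trace:
    """Subtract the drift estimate (linearly interpolated) from the record."""
    if len(drift.t) < 2:
        raise TraceError("drift estimate needs >= 2 points")
    dt_frame = float(np.median(np.diff(drift.t)))
    if drift.t[0] > trace.t[0] + dt_frame or drift.t[-1] < trace.t[-1] - dt_frame:
        raise TraceError(
            "drift estimate does not span the trace time range "
            f"([{drift.t[0]:g}, {drift.t[-1]:g}] vs [{trace.t[0]:g}, {trace.t[-1]:g}])"
        )
    d = np.interp(trace.t, drift.t, drift.d)
    out = trace.copy(x=trace.x - d)
    out.history.append(f"correct_drift: subtracted ({drift.smoothing or 'unsmoothed'})")
    return out


def qc_z_drift(tracks: list, threshold: float = 0.7):
    """Flag records whose correlation quality indicates out-of-plane drift.

    Defocus from Z drift lowers the cross-correlation peak against the
    in-focus reference ROI. The score is the mean peak quality across frames
    and markers; records scoring below ``threshold`` are flagged (never
    silently dropped).

    Returns
    -------
    (flagged: bool, score: float)
    """
    if len(tracks) == 0:
        raise TraceError("need at least one marker track")
    score = float(np.mean([tr.quality.mean() for tr in tracks]))
    return bool(score < threshold), score
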