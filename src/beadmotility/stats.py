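"""Group comparisons and dataset summaries.

Bootstrap two-sample tests on time-weighted exponential velocity means,
force-binned velocity fits (3.5 pN bins centered on zero load), and the
occupancy / bond-lifetime summary tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import DistFit, WeightingRule, fit_exponential_weighted
from .trace import TraceError

__all__ = [
    "BootstrapResult",
    "ForceBinSummary",
    "bootstrap_mean_test",
    "bootstrap_mean_test_segments",
    "bin_by_force",
    "summarize_dataset",
]


@dataclass
class BootstrapResult:
    """Two-sided bootstrap test of H0: mu_A = mu_B on weighted means."""

    observed_diff: float
    p_value: float
    B: int
    seed: int
    n_a: int
    n_b: int


@dataclass
class ForceBinSummary:
    """Per-force-bin time-weighted velocity fit."""

    bin_center: float  # pN
    bin_width: float
    fit: DistFit
    n_segments: int
    low_count: bool = False


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * values) / np.sum(weights))


def bootstrap_mean_test(
    values_a,
    weights_a,
    values_b,
    weights_b,
    B: int = 10000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test for a difference of time-weighted exponential means.

    The statistic is the difference of weighted MLE means. The null is built
    by rescaling each weighted sample to the pooled mean (the natural
    mean-shift for a positive scale family), resampling segments (with their
    weights) with replacement within groups, and taking the two-sided tail
    probability of |diff*| >= |observed|, with an add-one correction so
    p >= 1/(B+1).
    """
    if B < 100:
        raise TraceError("B must be >= 100 for a stable p-value")
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise TraceError("both groups must be non-empty")

    mu_a = _weighted_mean(va, wa)
    mu_b = _weighted_mean(vb, wb)
    observed = mu_a - mu_b
    mu_pool = float((np.sum(wa * va) + np.sum(wb * vb)) / (np.sum(wa) + np.sum(wb)))

    # rescale both groups onto the pooled mean (null hypothesis)
    va0 = va * (mu_pool / mu_a) if mu_a > 0 else va
    vb0 = vb * (mu_pool / mu_b) if mu_b > 0 else vb

    rng = np.random.default_rng(seed)
    ia = rng.integers(0, va.size, size=(B, va.size))
    ib = rng.integers(0, vb.size, size=(B, vb.size))
    sa = np.sum(wa[ia] * va0[ia], axis=1) / np.sum(wa[ia], axis=1)
    sb = np.sum(wb[ib] * vb0[ib], axis=1) / np.sum(wb[ib], axis=1)
    diffs = sa - sb
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= abs(observed))) / (B + 1.0)
    return BootstrapResult(
        observed_diff=observed,
        p_value=float(p),
        B=B,
        seed=seed,
        n_a=int(va.size),
        n_b=int(vb.size),
    )


def bootstrap_mean_test_segments(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    B: int = 10000,
    rule: WeightingRule | None = None,
    seed: int = 0,
    value_col: str = "v_rel",
) -> BootstrapResult:
    """Bootstrap test between two segment tables (|velocity|, time-weighted)."""
    rule = rule or WeightingRule()
    va = np.abs(group_a[value_col].to_numpy(dtype=float))
    vb = np.abs(group_b[value_col].to_numpy(dtype=float))
    wa = rule.weights(group_a["duration"].to_numpy())
    wb = rule.weights(group_b["duration"].to_numpy())
    return bootstrap_mean_test(va, wa, vb, wb, B=B, seed=seed)


def bin_by_force(
    segments: pd.DataFrame,
    width: float = 3.5,
    rule: WeightingRule | None = None,
    min_count: int = 5,
) -> list:
    """Bin forward moving segments by mean applied force and fit each bin.

    Bins are ``width``-pN wide and centered on zero load (edges at
    +/- width/2, +/- 3 width/2, ...). Each bin gets a time-weighted
    exponential velocity fit; bins with fewer than ``min_count`` segments
    are flagged ``low_count``; empty bins are omitted.
    """
    rule = rule or WeightingRule()
    if "mean_force" not in segments or segments["mean_force"].isna().all():
        raise TraceError("segments carry no force channel")
    sel = segments[
        (segments["direction"] == "forward")
        & (segments["state"] == "moving")
        & segments["retained"]
        & segments["mean_force"].notna()
    ]
    if sel.empty:
        return []
    k = np.round(sel["mean_force"].to_numpy(dtype=float) / width).astype(int)
    out = []
    for kk in sorted(set(k)):
        sub = sel[k == kk]
        fit = fit_exponential_weighted(
            np.abs(sub["v_rel"].to_numpy(dtype=float)),
            durations=sub["duration"].to_numpy(dtype=float),
            rule=rule,
        )
        out.append(
            ForceBinSummary(
                bin_center=float(kk * width),
                bin_width=width,
                fit=fit,
                n_segments=int(len(sub)),
                low_count=len(sub) < min_count,
            )
        )
    return out


def summarize_dataset(
    segments: pd.DataFrame,
    runs: pd.DataFrame | None = None,
    pauses: pd.DataFrame | None = None,
    record_durations: dict | None = None,
    lifetime_cutoff: float = 10.0,
) -> dict:
    """Occupancy fractions, run/pause counts and bond lifetimes.

    Occupancy is time-weighted over retained segments: fraction of time
    moving forward, moving backward, and paused (pauses carry no direction).
    Mean bond lifetime averages the durations of records longer than
    ``lifetime_cutoff`` seconds.
    """
    ret = segments[segments["retained"]]
    total = float(ret["duration"].sum())
    occ = {"forward": 0.0, "backward": 0.0, "paused": 0.0}
    if total > 0:
        fwd = ret[(ret["state"] == "moving") & (ret["direction"] == "forward")]
        bwd = ret[(ret["state"] == "moving") & (ret["direction"] == "backward")]
        pse = ret[ret["state"] == "paused"]
        occ = {
            "forward": float(fwd["duration"].sum()) / total,
            "backward": float(bwd["duration"].sum()) / total,
            "paused": float(pse["duration"].sum()) / total,
        }
        if abs(sum(occ.values()) - 1.0) > 1e-9:
            warnings.warn("occupancy fractions do not sum to 1", stacklevel=2)
    summary = {
        "occupancy": occ,
        "total_retained_time_s": total,
        "n_segments_retained": int(len(ret)),
        "n_segments_total": int(len(segments)),
    }
    if runs is not None:
        summary["n_runs"] = int(len(runs))
        for direction in ("forward", "backward"):
            sub = runs[runs["direction"] == direction]
            summary[f"n_runs_{direction}"] = int(len(sub))
    if pauses is not None:
        summary["n_pauses"] = int(len(pauses))
    if record_durations:
        durs = np.asarray(list(record_durations.values()), dtype=float)
        kept = durs[durs > lifetime_cutoff]
        summary["n_records"] = int(len(durs))
        summary["total_observation_time_s"] = float(durs.sum())
        summary["mean_bond_lifetime_s"] = float(kept.mean()) if kept.size else np.nan
        summary["n_records_lifetime"] = int(kept.size)
    return summary
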