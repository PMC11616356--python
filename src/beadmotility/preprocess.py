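"""Raw-record conditioning: decimation, EWMA smoothing, downsampling.

Records are decimated to the working rate (anti-alias low-pass then rate
reduction), smoothed with a causal exponentially weighted moving average
(window 20 points), and downsampled by a factor of 100 before drift
correction and segmentation.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .trace import Trace, TraceError

__all__ = ["decimate", "ewma", "downsample"]


def decimate(trace: Trace, target_rate: float) -> Trace:
    """Reduce the sampling rate with zero-phase anti-alias filtering.

    Uses polyphase resampling (FIR low-pass at the output Nyquist applied
    symmetrically, so no phase delay). Never upsamples.
    """
    if target_rate <= 0:
        raise TraceError("target_rate must be positive")
    if target_rate > trace.sample_rate * (1 + 1e-9):
        raise TraceError(
            f"cannot decimate {trace.sample_rate} Hz to {target_rate} Hz (upsampling)"
        )
    if abs(target_rate - trace.sample_rate) <= 1e-9 * trace.sample_rate:
        return trace.with_history("decimate: no-op (already at target rate)")

    ratio = Fraction(target_rate / trace.sample_rate).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator

    def _resample(y):
        # detrend by the OLS line so constants and ramps pass through exactly
        # (FIR passband ripple would otherwise leave ~1e-4 relative error)
        coef = np.polyfit(trace.t, y, 1)
        resid = y - np.polyval(coef, trace.t)
        out = signal.resample_poly(resid, up, down, padtype="line")
        tt = trace.t[0] + np.arange(len(out)) / target_rate
        return out + np.polyval(coef, tt), tt

    x, t = _resample(trace.x)
    f = None if trace.f is None else _resample(trace.f)[0]
    out = Trace(
        t=t,
        x=x,
        f=f,
        sample_rate=target_rate,
        meta=dict(trace.meta),
        history=list(trace.history),
    )
    out.history.append(f"decimate: {trace.sample_rate:g} Hz -> {target_rate:g} Hz")
    return out


def ewma(trace: Trace, window: int = 20) -> Trace:
    """Causal exponentially weighted moving average.

    Single-pass recursive filter with decay ``alpha = 2 / (window + 1)``,
    initialized at the first sample, so a constant trace is unchanged.
    """
    if window < 1:
        raise TraceError("window must be >= 1")
    if window == 1:
        return trace.with_history("ewma: window=1 (identity)")
    alpha = 2.0 / (window + 1.0)
    # y[k] = (1-a) y[k-1] + a x[k]  via lfilter with y[0] forced to x[0]
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = np.array([(1.0 - alpha) * trace.x[0]])
    x, _ = signal.lfilter(b, a, trace.x, zi=zi)
    out = trace.copy(x=x)
    out.history.append(f"ewma: window={window} (causal, alpha={alpha:.6g})")
    return out


def downsample(trace: Trace, factor: int = 100) -> Trace:
    """Keep every ``factor``-th sample; sample rate divided by ``factor``."""
    if factor < 1 or int(factor) != factor:
        raise TraceError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace.with_history("downsample: factor=1 (identity)")
    if factor >= len(trace):
        raise TraceError(
            f"downsample factor {factor} exceeds record length {len(trace)}"
        )
    out = Trace(
        t=trace.t[::factor].copy(),
        x=trace.x[::factor].copy(),
        f=None if trace.f is None else trace.f[::factor].copy(),
        sample_rate=trace.sample_rate / factor,
        meta=dict(trace.meta),
        history=list(trace.history),
    )
    out.history.append(f"downsample: factor={factor}")
    return out
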