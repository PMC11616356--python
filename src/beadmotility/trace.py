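"""Core bead-position record container.

A :class:`Trace` is a uniformly sampled time series of bead position along
the motility axis (nm), with an optional per-sample force channel (pN,
assisting load positive) and experiment metadata.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "TraceError"]

#: relative tolerance on sample spacing uniformity
_UNIFORM_RTOL = 1e-9


class TraceError(ValueError):
    """Raised for malformed or inconsistent trace data."""


@dataclass
class Trace:
    """Uniformly sampled bead position record.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and uniform.
    x : ndarray
        Bead position in nm projected on the motility axis.
    sample_rate : float
        Sampling rate in Hz. Must match the spacing of ``t``.
    f : ndarray, optional
        Per-sample force in pN; assisting load is positive.
    meta : dict
        Record metadata: ``record_id``, ``substrate`` (CI/CIII/FP),
        ``construct`` (intact/CD-only/control), ``temperature_c``.
    history : list of str
        Append-only processing history.
    """

    t: np.ndarray
    x: np.ndarray
    sample_rate: float
    f: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.f is not None:
            self.f = np.asarray(self.f, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self):
        if self.sample_rate <= 0:
            raise TraceError("sample_rate must be positive")
        if self.t.ndim != 1 or self.x.ndim != 1:
            raise TraceError("t and x must be 1-D")
        if len(self.t) != len(self.x):
            raise TraceError(
                f"t and x length mismatch ({len(self.t)} != {len(self.x)})"
            )
        if self.f is not None and len(self.f) != len(self.t):
            raise TraceError("force channel length mismatch")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise TraceError("t must be strictly increasing")
            period = 1.0 / self.sample_rate
            if not np.allclose(dt, period, rtol=_UNIFORM_RTOL, atol=_UNIFORM_RTOL * period):
                raise TraceError("t must be uniform and consistent with sample_rate")

    # -- convenience ------------------------------------------------------
    def __len__(self):
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last sample)."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def record_id(self) -> str:
        return str(self.meta.get("record_id", ""))

    def copy(self, **updates) -> "Trace":
        """Shallow-config, deep-data copy with optional field overrides."""
        kw = dict(
            t=self.t.copy(),
            x=self.x.copy(),
            sample_rate=self.sample_rate,
            f=None if self.f is None else self.f.copy(),
            meta=dict(self.meta),
            history=list(self.history),
        )
        kw.update(updates)
        return Trace(**kw)

    def with_history(self, entry: str) -> "Trace":
        out = self.copy()
        out.history.append(entry)
        return out

    def slice_time(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace covering [t_start, t_end]."""
        sel = (self.t >= t_start) & (self.t <= t_end)
        if not np.any(sel):
            raise TraceError("empty time slice")
        return Trace(
            t=self.t[sel],
            x=self.x[sel],
            sample_rate=self.sample_rate,
            f=None if self.f is None else self.f[sel],
            meta=dict(self.meta),
            history=list(self.history),
        )


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return dict(obj)
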