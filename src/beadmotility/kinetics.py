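"""Distribution fitting and event detection for motility kinetics.

Implements the study's estimators: time-weighted exponential velocity PDFs
(maximum likelihood over [0, inf), each segment's velocity replicated
N_R = floor(duration / 10 s) times), two-parameter left-truncated exponential
dwell-time fits (all probability on [t0, inf)), a two-component truncated
exponential mixture fitted by Expectation-Maximization, the control-derived
pause velocity threshold, and detection of abrupt (>= 5 nm, millisecond)
displacements in full-rate records.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .trace import Trace, TraceError

__all__ = [
    "DistFit",
    "WeightingRule",
    "JumpEvent",
    "fit_exponential_weighted",
    "fit_truncated_exponential",
    "fit_double_exponential_em",
    "derive_pause_threshold",
    "detect_jumps",
    "remove_jumps",
]


@dataclass
class WeightingRule:
    """Time weighting of segment observations: N_R = floor(duration / basis)."""

    basis: float = 10.0  # s

    def weights(self, durations) -> np.ndarray:
        d = np.asarray(durations, dtype=float)
        w = np.floor(d / self.basis).astype(int)
        if np.any(w < 1):
            raise TraceError(
                f"all durations must be >= the weighting basis ({self.basis} s)"
            )
        return w


@dataclass
class DistFit:
    """Result of a distribution fit.

    ``family`` is one of ``exp`` (mean mu), ``trunc_exp`` (tau, t0) or
    ``trunc_2exp`` (A1, t1, A2, t2, t0 with A1 + A2 = 1 and t1 <= t2).
    ``n`` is the unweighted observation count (the reported N convention);
    ``n_effective`` the weighted count used for likelihood-based intervals.
    """

    family: str
    params: dict
    ci95: dict = field(default_factory=dict)
    n: int = 0
    n_effective: float = 0.0
    loglik: float = np.nan
    n_iter: int | None = None
    converged: bool = True
    notes: str = ""


def _exp_mean_ci(mean: float, n_eff: float, alpha: float = 0.05):
    """Exact CI for an exponential mean: 2 n xbar / mu ~ chi2(2n)."""
    if mean <= 0 or n_eff <= 0:
        return (np.nan, np.nan)
    lo = 2.0 * n_eff * mean / sstats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * n_eff)
    hi = 2.0 * n_eff * mean / sstats.chi2.ppf(alpha / 2.0, 2.0 * n_eff)
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def fit_exponential_weighted(
    values,
    durations=None,
    rule: WeightingRule | None = None,
    *,
    weights=None,
    floor: float = 0.0,
    independent_count: float | None = None,
) -> DistFit:
    """Time-weighted exponential MLE over [floor, inf).

    The MLE of the exponential mean on the weight-replicated sample is the
    closed-form weighted mean ``mu = sum(N_R * (v - floor)) / sum(N_R)``.
    With ``floor=0`` this is the plain [0, inf) fit used for velocity PDFs
    and control records; a positive floor fits the same exponential
    left-truncated at the pause threshold (identical mean parameter by
    memorylessness), used when pause-classified segments are excluded.

    ``n`` excludes weight replication and ``n_effective = sum(N_R)``. The
    95% CI uses the exponential likelihood evaluated at a cluster-corrected
    count: weight replication duplicates one observed velocity rather than
    adding draws, so the default CI count is ``(sum w)^2 / sum(w^2)`` (equal
    to n for equal weights). Callers pooling segmentation replicates of the
    same records should divide further via ``independent_count``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise TraceError("empty sample")
    if np.any(v < floor - 1e-12):
        raise TraceError(f"all values must be >= the fit domain floor ({floor})")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif durations is not None:
        w = (rule or WeightingRule()).weights(durations).astype(float)
    else:
        w = np.ones_like(v)
    if len(w) != len(v):
        raise TraceError("values and weights length mismatch")
    n_eff = float(w.sum())
    mu = float(np.sum(w * (v - floor)) / n_eff)
    if mu <= 0:
        warnings.warn("degenerate exponential fit (mean 0)", stacklevel=2)
        loglik = -np.inf
    else:
        loglik = float(np.sum(w * (-np.log(mu) - (v - floor) / mu)))
    if independent_count is None:
        independent_count = n_eff**2 / float(np.sum(w * w))
    independent_count = max(float(independent_count), 1.0)
    return DistFit(
        family="exp",
        params={"mean": mu, "floor": floor},
        ci95={"mean": _exp_mean_ci(mu, independent_count)},
        n=int(v.size),
        n_effective=n_eff,
        loglik=loglik,
        notes=f"ci_count={independent_count:.1f}",
    )


def fit_truncated_exponential(
    durations, t0: float = 10.0, *, independent_count: float | None = None
) -> DistFit:
    """Two-parameter truncated exponential MLE on [t0, inf).

    Density f(t) = (1/tau) exp(-(t - t0)/tau); the MLE is
    ``tau = mean(durations) - t0`` exactly. Both ``tau`` and the distribution
    mean ``t0 + tau`` are reported. ``independent_count`` overrides the CI
    sample count when the sample pools segmentation replicates of the same
    records.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise TraceError("empty sample")
    if np.any(d < t0 - 1e-12):
        raise TraceError(f"all durations must be >= t0 ({t0} s)")
    n_ci = float(d.size) if independent_count is None else max(float(independent_count), 1.0)
    tau = float(d.mean() - t0)
    notes = ""
    if tau <= 0:
        warnings.warn("degenerate truncated-exponential fit (tau = 0)", stacklevel=2)
        notes = "degenerate: all durations at t0"
        loglik = -np.inf
    else:
        loglik = float(np.sum(-np.log(tau) - (d - t0) / tau))
    ci_tau = _exp_mean_ci(tau, n_ci)
    return DistFit(
        family="trunc_exp",
        params={"tau": tau, "t0": t0, "mean": t0 + tau},
        ci95={"tau": ci_tau, "mean": (t0 + ci_tau[0], t0 + ci_tau[1])},
        n=int(d.size),
        n_effective=float(d.size),
        loglik=loglik,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# EM mixture
# ---------------------------------------------------------------------------

def _mixture_loglik(s: np.ndarray, A: np.ndarray, tau: np.ndarray) -> float:
    dens = np.sum(A[None, :] / tau[None, :] * np.exp(-s[:, None] / tau[None, :]), axis=1)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_double_exponential_em(
    durations,
    t0: float = 10.0,
    tol: float = 1e-5,
    max_iter: int = 50000,
    n_components: int = 2,
) -> DistFit:
    """EM fit of a t0-truncated exponential mixture to dwell times.

    Each component has density (1/t_k) exp(-(t - t0)/t_k) on [t0, inf);
    amplitudes sum to 1. Iteration stops when every component-mean update
    changes by less than ``tol`` (seconds). The log-likelihood is
    non-decreasing; components are reported with t1 <= t2. With one
    component the EM collapses to the truncated single-exponential MLE.
    """
    d = np.asarray(durations, dtype=float)
    if np.any(d < t0 - 1e-12):
        raise TraceError(f"all durations must be >= t0 ({t0} s)")
    if n_components == 1:
        fit = fit_truncated_exponential(d, t0=t0)
        fit.n_iter = 1
        return fit
    if d.size < 4:
        raise TraceError("need >= 4 observations for a two-component fit")
    s = d - t0

    # initialization from the 25th/75th percentiles of the shifted sample
    q25, q75 = np.percentile(s, [25.0, 75.0])
    tau = np.array([max(q25, tol), max(q75, 2.0 * max(q25, tol))], dtype=float)
    if tau[1] - tau[0] < tol:
        tau[1] = tau[0] * 2.0 + tol
    A = np.array([0.5, 0.5])

    loglik = _mixture_loglik(s, A, tau)
    logliks = [loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        comp = A[None, :] / tau[None, :] * np.exp(-s[:, None] / tau[None, :])
        total = np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
        r = comp / total
        # M step
        wsum = r.sum(axis=0)
        if np.any(wsum < 1e-12):
            break  # component collapse
        new_tau = (r * s[:, None]).sum(axis=0) / wsum
        new_A = wsum / s.size
        delta = np.abs(new_tau - tau)
        tau, A = new_tau, new_A
        loglik = _mixture_loglik(s, A, tau)
        logliks.append(loglik)
        if np.all(delta < tol):
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {it} iterations", stacklevel=2)

    order = np.argsort(tau)
    tau, A = tau[order], A[order]
    degenerate = A[1] < 1e-6 or A[0] < 1e-6 or (tau[1] - tau[0]) < 1e-6 * max(tau[1], 1.0)
    notes = "degenerate: equivalent to single truncated exponential" if degenerate else ""

    ci95 = _em_ci(s, A, tau)
    return DistFit(
        family="trunc_2exp",
        params={
            "A1": float(A[0]),
            "t1": float(tau[0]),
            "A2": float(A[1]),
            "t2": float(tau[1]),
            "t0": t0,
            "mean1": float(t0 + tau[0]),
            "mean2": float(t0 + tau[1]),
        },
        ci95=ci95,
        n=int(d.size),
        n_effective=float(d.size),
        loglik=loglik,
        n_iter=it,
        converged=converged,
        notes=notes,
    )


def _em_ci(s: np.ndarray, A: np.ndarray, tau: np.ndarray) -> dict:
    """Wald 95% CIs from a finite-difference observed information matrix."""
    theta = np.array([A[0], tau[0], tau[1]])

    def nll(th):
        a1, t1, t2 = th
        if not (0 < a1 < 1) or t1 <= 0 or t2 <= 0:
            return np.inf
        return -_mixture_loglik(s, np.array([a1, 1 - a1]), np.array([t1, t2]))

    h = np.maximum(1e-4 * np.abs(theta), 1e-6)
    H = np.zeros((3, 3))
    f0 = nll(theta)
    try:
        for i in range(3):
            for j in range(i, 3):
                ei = np.zeros(3); ei[i] = h[i]
                ej = np.zeros(3); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + f0
                ) / (h[i] * h[j])
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except (np.linalg.LinAlgError, FloatingPointError):
        se = np.full(3, np.nan)
    z = 1.959963984540054
    return {
        "A1": (float(theta[0] - z * se[0]), float(theta[0] + z * se[0])),
        "t1": (float(theta[1] - z * se[1]), float(theta[1] + z * se[1])),
        "t2": (float(theta[2] - z * se[2]), float(theta[2] + z * se[2])),
    }


# ---------------------------------------------------------------------------
# pause threshold
# ---------------------------------------------------------------------------

def derive_pause_threshold(control_fit, quantile: float = 0.90) -> float:
    """Velocity below which ``quantile`` of fixed-tether segments fall.

    For an exponential speed PDF with mean mu the q-quantile is
    ``mu * ln(1 / (1 - q))``; at q = 0.90 and the control mean 0.037 nm/s
    this is the 0.085 nm/s motility cutoff.
    """
    if not (0.0 < quantile < 1.0):
        raise TraceError("quantile must be in (0, 1)")
    if isinstance(control_fit, DistFit):
        if control_fit.family != "exp":
            raise TraceError("pause threshold requires an exponential control fit")
        mu = control_fit.params["mean"]
    else:
        mu = float(control_fit)
    return float(mu * np.log(1.0 / (1.0 - quantile)))


# ---------------------------------------------------------------------------
# abrupt displacement (jump) detection
# ---------------------------------------------------------------------------

@dataclass
class JumpEvent:
    """One detected abrupt displacement."""

    t: float  # s, localized edge time
    amplitude: float  # nm, signed plateau-to-plateau difference
    transition_time: float  # s, 10%-90% equivalent rise time
    index: int = 0
    reversible_partner: int | None = None  # index of the paired opposite event


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_jumps(
    trace: Trace,
    min_amplitude: float = 5.0,
    max_transition: float = 0.01,
    *,
    plateau_window: float = 0.05,
    pair_window: float = 10.0,
    pair_amp_tol: float = 0.2,
) -> list:
    """Detect abrupt position changes in a full-rate record.

    A matched plateau filter (mean over ``plateau_window`` after minus mean
    before, separated by a guard gap of ``max_transition``) flags candidate
    edges; each is kept if the plateau-to-plateau amplitude reaches
    ``min_amplitude`` and the 10-90% equivalent rise time (twice the 25-75%
    crossing interval of the locally smoothed trace) does not exceed
    ``max_transition``. Opposite-sign events of similar amplitude (within
    ``pair_amp_tol``) within ``pair_window`` seconds are marked as
    reversible partners.
    """
    fs = trace.sample_rate
    x = trace.x
    n = len(x)
    w = max(3, int(round(plateau_window * fs)))
    g = max(1, int(round(max_transition * fs)))
    if n < 2 * (w + g) + 1:
        return []

    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(w + g, n - w - g)
    m_before = (c[idx - g] - c[idx - g - w]) / w
    m_after = (c[idx + g + w] - c[idx + g]) / w
    d = m_after - m_before

    mask = np.abs(d) >= 0.7 * min_amplitude
    cand = idx[mask]
    if cand.size == 0:
        return []
    splits = np.flatnonzero(np.diff(cand) > w) + 1
    clusters = np.split(cand, splits)

    y = _boxcar(x, max(3, int(round(0.001 * fs))))
    events = []
    for cluster in clusters:
        dvals = d[cluster - (w + g)]
        i_star = int(cluster[np.argmax(np.abs(dvals))])
        pre = float((c[i_star - g] - c[i_star - g - w]) / w)
        post = float((c[i_star + g + w] - c[i_star + g]) / w)
        amp = post - pre
        if abs(amp) < min_amplitude:
            continue
        transition = _rise_time(y, trace.t, i_star, pre, amp, w, g, fs)
        if np.isfinite(transition) and transition > max_transition:
            continue
        events.append(
            JumpEvent(
                t=float(trace.t[i_star]),
                amplitude=amp,
                transition_time=transition,
                index=len(events),
            )
        )

    _pair_reversible(events, pair_window, pair_amp_tol)
    return events


def _rise_time(y, t, i_star, pre, amp, w, g, fs):
    """10-90% equivalent transition time: 2x the 25-75% crossing interval."""
    a = max(i_star - g - w // 2, 0)
    b = min(i_star + g + w // 2, len(y))
    seg = y[a:b]
    lo = pre + 0.25 * amp
    hi = pre + 0.75 * amp
    sgn = 1.0 if amp > 0 else -1.0
    above_hi = sgn * seg >= sgn * hi
    if not above_hi.any():
        return np.inf
    i_hi = int(np.argmax(above_hi))
    below_lo = sgn * seg[: i_hi + 1] <= sgn * lo
    if not below_lo.any():
        i_lo = 0
    else:
        i_lo = int(len(below_lo) - 1 - np.argmax(below_lo[::-1]))
    dt_samples = max(i_hi - i_lo, 1)
    return 2.0 * dt_samples / fs


def _pair_reversible(events: list, pair_window: float, pair_amp_tol: float):
    for i, ev in enumerate(events):
        if ev.reversible_partner is not None:
            continue
        for j in range(i + 1, len(events)):
            other = events[j]
            if other.reversible_partner is not None:
                continue
            if other.t - ev.t > pair_window:
                break
            opposite = np.sign(other.amplitude) == -np.sign(ev.amplitude)
            similar = abs(abs(other.amplitude) - abs(ev.amplitude)) <= pair_amp_tol * abs(
                ev.amplitude
            )
            if opposite and similar:
                ev.reversible_partner = other.index
                other.reversible_partner = ev.index
                break


def remove_jumps(trace: Trace, events: list) -> Trace:
    """Subtract detected jump steps so segmentation is not split or biased.

    Each event is modeled as an ideal step of its fitted amplitude at its
    localized time; the summed step function is subtracted from the record.
    """
    if not events:
        return trace.with_history("remove_jumps: no events")
    x = trace.x.copy()
    for ev in events:
        x[trace.t >= ev.t] -= ev.amplitude
    out = trace.copy(x=x)
    out.history.append(f"remove_jumps: subtracted {len(events)} step(s)")
    return out
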