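"""Synthetic bead-trace generator with ground truth.

Emulates tethered-bead optical-tweezers records of a processive cellulase:
piecewise-constant motility with forward/backward/pause states switched by a
continuous-time Markov chain, exponentially distributed per-visit speeds,
slow instrumental drift, rare abrupt (5-20 nm, millisecond) displacements,
and i.i.d. Gaussian position noise at the acquisition bandwidth. Enzyme-free
control records and fiducial-marker video frames are generated with the same
machinery so that every downstream analysis stage can be validated against
known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .trace import Trace

__all__ = [
    "SimConfig",
    "SimTruth",
    "JumpTruth",
    "simulate_motility_record",
    "simulate_control_record",
    "simulate_fiducial_frames",
]

STATE_NAMES = ("forward", "backward", "pause")

# Logistic transitions are parameterized by their 1%-99% span; the logistic
# scale is span / (2 * ln 99).
_LOGISTIC_SPAN_FACTOR = 2.0 * math.log(99.0)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Generative model parameters for one synthetic record.

    Defaults reproduce the reference study conditions: 3 kHz sampling,
    forward/backward mean speeds 0.17 / 0.11 nm/s, forward/backward/pause
    time occupancies 0.41 / 0.20 / 0.39, residual drift scale 0.037 nm/s,
    and a 1010 bp (343 nm) DNA tether.

    Notes
    -----
    ``state_means`` are the exponential dwell-time parameters (tau) of each
    state. The analysis pipeline retains only segments longer than 10 s and
    reports truncated-fit means t0 + tau, so tau = 15 s corresponds to
    reported dwell means of ~25 s.

    Moving-state speeds are drawn as ``motile_speed_floor + Exp(mean)`` --
    the exponential with the configured mean conditioned on exceeding the
    detection floor (the same distribution above the floor, by
    memorylessness). Sub-floor motility is indistinguishable from a pause,
    so the generator does not produce it in moving states; pause states
    carry small random-sign residual motion instead.
    """

    sample_rate: float = 3000.0  # Hz
    duration: float = 137.6  # s; 22 such records span the 3027 s reference dataset
    state_means: tuple = (15.0, 15.0, 15.0)  # s, exponential dwell tau per state
    occupancy_targets: tuple = (0.41, 0.20, 0.39)  # time fractions f/b/p
    v_forward_mean: float = 0.17  # nm/s
    v_backward_mean: float = 0.11  # nm/s
    pause_speed_mean: float = 0.03  # nm/s residual motion in pauses, random sign
    motile_speed_floor: float = 0.085  # nm/s, minimum moving-state speed
    noise_sd: float = 2.0  # nm per sample at full bandwidth
    drift_rate_scale: float = 0.037  # nm/s, |straight-line slope| scale of drift
    drift_wander_frac: float = 0.25  # wander velocity SD relative to drift scale
    drift_corr_time: float = 30.0  # s, correlation time of the wander velocity
    jump_rate: float = 0.005  # events / s
    jump_amp_range: tuple = (5.0, 20.0)  # nm
    jump_risetime_range: tuple = (0.001, 0.01)  # s (1%-99% span)
    jump_reversible_fraction: float = 0.3
    jump_pair_delay_range: tuple = (0.5, 5.0)  # s between a jump and its partner
    tether_contour: float = 343.0  # nm (1010 bp x 0.34 nm/bp)
    trap_stiffness: float | None = None  # pN/nm; enables the force channel
    substrate: str = "CI"
    construct: str = "intact"
    temperature_c: float = 21.0
    record_id: str = "sim-000"
    seed: int = 0
    #: optional explicit state path [(t_start, t_end, state_name, velocity), ...]
    #: overriding the Markov draw (deterministic motility for validation)
    forced_state_path: list | None = None

    def validate(self):
        if self.duration <= 0:
            raise SimConfigError("duration must be > 0")
        if self.sample_rate <= 0:
            raise SimConfigError("sample_rate must be > 0")
        occ = np.asarray(self.occupancy_targets, dtype=float)
        if occ.shape != (3,) or np.any(occ < 0):
            raise SimConfigError("occupancy_targets must be 3 non-negative fractions")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise SimConfigError("occupancy_targets must sum to 1 within 1e-9")
        if np.any(np.asarray(self.state_means, dtype=float) <= 0):
            raise SimConfigError("state dwell means must be strictly positive")
        for name in ("v_forward_mean", "v_backward_mean", "pause_speed_mean"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be strictly positive")
        if self.noise_sd < 0 or self.drift_rate_scale < 0 or self.jump_rate < 0:
            raise SimConfigError("noise/drift/jump scales must be non-negative")
        if self.jump_amp_range[0] < 0 or self.jump_amp_range[1] < self.jump_amp_range[0]:
            raise SimConfigError("jump_amp_range must be an ordered non-negative range")
        if self.jump_risetime_range[0] <= 0:
            raise SimConfigError("jump rise times must be strictly positive")
        return self


@dataclass
class JumpTruth:
    """Ground truth for one injected abrupt displacement."""

    t: float  # s, transition midpoint
    amplitude: float  # nm, signed
    risetime: float  # s, 1%-99% span of the logistic transition
    partner: int | None = None  # index of the opposite-sign partner event


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic record.

    ``state_path`` tiles [0, duration] with (t_start, t_end, state, velocity)
    tuples; ``drift_t``/``drift_d`` sample the injected drift displacement;
    ``jump_events`` lists the injected abrupt displacements.
    """

    state_path: list  # [(t_start, t_end, state_name, velocity_nm_s), ...]
    drift_t: np.ndarray
    drift_d: np.ndarray
    jump_events: list = field(default_factory=list)
    net_displacement: float = 0.0

    def motility_at(self, t: np.ndarray) -> np.ndarray:
        """Noise-free motility displacement (state path only) at times t."""
        knots_t, knots_x = _state_path_knots(self.state_path)
        return np.interp(t, knots_t, knots_x)

    def drift_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.drift_t, self.drift_d)

    def jumps_at(self, t: np.ndarray) -> np.ndarray:
        return _jump_signal(t, self.jump_events)

    def clean_position(self, t: np.ndarray) -> np.ndarray:
        """Trace position minus noise: motility + drift + jumps."""
        return self.motility_at(t) + self.drift_at(t) + self.jumps_at(t)


# ---------------------------------------------------------------------------
# state process
# ---------------------------------------------------------------------------

def embedded_transition_matrix(occupancies, dwell_means, n_iter: int = 500) -> np.ndarray:
    """Zero-diagonal jump-chain transition matrix with prescribed occupancy.

    For a semi-Markov process with exponential dwells of mean ``dwell_means[i]``,
    time occupancy is proportional to (visit frequency) x (dwell mean), so the
    embedded chain must have stationary distribution
    ``w_i ~ occ_i / dwell_means[i]``. The matrix is obtained by iterative
    proportional fitting of a zero-diagonal flux matrix to equal row and
    column margins w (feasible when max(w) <= 1/2).
    """
    occ = np.asarray(occupancies, dtype=float)
    m = occ / np.asarray(dwell_means, dtype=float)
    w = m / m.sum()
    if w.max() > 0.5 + 1e-12:
        raise SimConfigError(
            "occupancy/dwell combination not realizable by a chain without "
            f"self-transitions (embedded stationary max {w.max():.3f} > 0.5)"
        )
    flux = np.outer(w, w)
    np.fill_diagonal(flux, 0.0)
    for _ in range(n_iter):
        flux *= (w / flux.sum(axis=1))[:, None]
        flux *= w / flux.sum(axis=0)
    P = flux / flux.sum(axis=1, keepdims=True)
    return P


def _draw_state_path(config: SimConfig, rng: np.random.Generator) -> list:
    """Sample (t_start, t_end, state_index, velocity) tuples tiling [0, T]."""
    occ = np.asarray(config.occupancy_targets, dtype=float)
    means = np.asarray(config.state_means, dtype=float)
    P = embedded_transition_matrix(occ, means)
    # exponential dwells are memoryless: starting a fresh dwell in a state
    # drawn from the time-stationary occupancy is exactly stationary
    state = int(rng.choice(3, p=occ))
    path = []
    t = 0.0
    T = config.duration
    while t < T:
        dwell = rng.exponential(means[state])
        t_end = min(t + dwell, T)
        v = _draw_speed(state, config, rng)
        path.append((t, t_end, state, v))
        t += dwell
        state = int(rng.choice(3, p=P[state]))
    return path


def _draw_speed(state: int, config: SimConfig, rng: np.random.Generator) -> float:
    if state == 0:  # forward (+x by generator convention)
        return config.motile_speed_floor + rng.exponential(config.v_forward_mean)
    if state == 1:  # backward
        return -(config.motile_speed_floor + rng.exponential(config.v_backward_mean))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * rng.exponential(config.pause_speed_mean)


def _check_tiling(path, duration, tol: float = 1e-9):
    t = 0.0
    for t0, t1, _s, _v in path:
        if abs(t0 - t) > tol or t1 <= t0:
            raise SimConfigError("forced_state_path must tile [0, duration] in order")
        t = t1
    if abs(t - duration) > tol:
        raise SimConfigError("forced_state_path must end at duration")


def _state_path_knots(path):
    knots_t = [path[0][0]]
    knots_x = [0.0]
    x = 0.0
    for t0, t1, _state, v in path:
        x += v * (t1 - t0)
        knots_t.append(t1)
        knots_x.append(x)
    return np.asarray(knots_t), np.asarray(knots_x)


# ---------------------------------------------------------------------------
# drift and jumps
# ---------------------------------------------------------------------------

def _draw_drift(config: SimConfig, rng: np.random.Generator):
    """Slow drift displacement sampled on a 1 Hz grid.

    A per-record random linear component with E|slope| = drift_rate_scale
    plus an integrated low-pass (OU-velocity) wander of fractional amplitude
    ``drift_wander_frac``, so a straight-line fit over the record has
    |slope| ~= drift_rate_scale.
    """
    dt = 1.0
    tg = np.arange(0.0, config.duration + dt, dt)
    if config.drift_rate_scale == 0.0:
        return tg, np.zeros_like(tg)
    # E|N(0, sigma)| = sigma * sqrt(2/pi)
    slope_sd = config.drift_rate_scale * math.sqrt(math.pi / 2.0)
    slope = rng.normal(0.0, slope_sd)
    # OU velocity wander
    tau = config.drift_corr_time
    sd_v = config.drift_wander_frac * config.drift_rate_scale
    a = math.exp(-dt / tau)
    innov = rng.normal(0.0, sd_v * math.sqrt(1.0 - a * a), size=len(tg))
    v = np.empty(len(tg))
    v[0] = rng.normal(0.0, sd_v)
    for k in range(1, len(tg)):
        v[k] = a * v[k - 1] + innov[k]
    d = slope * tg + np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    return tg, d - d[0]


def _draw_jumps(config: SimConfig, rng: np.random.Generator) -> list:
    if config.jump_rate <= 0:
        return []
    n = rng.poisson(config.jump_rate * config.duration)
    events = []
    for _ in range(n):
        t0 = rng.uniform(0.0, config.duration)
        amp = rng.uniform(*config.jump_amp_range) * (1.0 if rng.random() < 0.5 else -1.0)
        rise = rng.uniform(*config.jump_risetime_range)
        events.append(JumpTruth(t=t0, amplitude=amp, risetime=rise))
        if rng.random() < config.jump_reversible_fraction:
            delay = rng.uniform(*config.jump_pair_delay_range)
            if t0 + delay < config.duration:
                i, j = len(events) - 1, len(events)
                events.append(
                    JumpTruth(t=t0 + delay, amplitude=-amp, risetime=rise, partner=i)
                )
                events[i].partner = j
    events_sorted = sorted(range(len(events)), key=lambda k: events[k].t)
    remap = {old: new for new, old in enumerate(events_sorted)}
    out = []
    for old in events_sorted:
        ev = events[old]
        out.append(
            JumpTruth(
                t=ev.t,
                amplitude=ev.amplitude,
                risetime=ev.risetime,
                partner=None if ev.partner is None else remap[ev.partner],
            )
        )
    return out


def _jump_signal(t: np.ndarray, events: list) -> np.ndarray:
    out = np.zeros_like(np.asarray(t, dtype=float))
    for ev in events:
        scale = ev.risetime / _LOGISTIC_SPAN_FACTOR
        out += ev.amplitude * expit((t - ev.t) / scale)
    return out


# ---------------------------------------------------------------------------
# record generators
# ---------------------------------------------------------------------------

def _sample_times(config: SimConfig) -> np.ndarray:
    n = int(round(config.duration * config.sample_rate))
    return np.arange(n) / config.sample_rate


def _finish_trace(config: SimConfig, t, x, origin: str) -> Trace:
    f = None if config.trap_stiffness is None else config.trap_stiffness * x
    return Trace(
        t=t,
        x=x,
        f=f,
        sample_rate=config.sample_rate,
        meta={
            "record_id": config.record_id,
            "substrate": config.substrate,
            "construct": config.construct,
            "temperature_c": config.temperature_c,
        },
        history=[origin],
    )


def simulate_motility_record(config: SimConfig):
    """Generate one synthetic motility record and its ground truth.

    Position = piecewise-linear motility (3-state Markov switching) + slow
    drift + abrupt jumps + i.i.d. Gaussian noise. The drift component is the
    stage/instrument drift that fiducial markers also see (and that drift
    correction removes).

    Returns
    -------
    (Trace, SimTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = _sample_times(config)

    if config.forced_state_path is not None:
        state_path = [tuple(seg) for seg in config.forced_state_path]
        _check_tiling(state_path, config.duration)
    else:
        path_idx = _draw_state_path(config, rng)
        state_path = [(t0, t1, STATE_NAMES[s], v) for (t0, t1, s, v) in path_idx]
    drift_t, drift_d = _draw_drift(config, rng)
    jumps = _draw_jumps(config, rng)

    net = sum(v * (t1 - t0) for (t0, t1, _s, v) in state_path)
    net += sum(ev.amplitude for ev in jumps)
    truth = SimTruth(
        state_path=state_path,
        drift_t=drift_t,
        drift_d=drift_d,
        jump_events=jumps,
        net_displacement=net,
    )

    x = truth.motility_at(t) + truth.drift_at(t) + _jump_signal(t, jumps)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=len(t))
    return _finish_trace(config, t, x, "simulate_motility_record"), truth


def simulate_control_record(config: SimConfig):
    """Generate one enzyme-free (fixed-tether) control record.

    No motility states and no jumps: only residual drift at
    ``drift_rate_scale`` (the post-correction scale -- this drift is local to
    the bead and *not* visible to fiducial markers) plus position noise.
    The truth state path is a single "fixed" interval.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = _sample_times(config)
    drift_t, drift_d = _draw_drift(config, rng)
    truth = SimTruth(
        state_path=[(0.0, config.duration, "fixed", 0.0)],
        drift_t=drift_t,
        drift_d=drift_d,
        jump_events=[],
        net_displacement=0.0,
    )
    x = truth.drift_at(t)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=len(t))
    return _finish_trace(config, t, x, "simulate_control_record"), truth


# ---------------------------------------------------------------------------
# fiducial-marker video
# ---------------------------------------------------------------------------

def simulate_fiducial_frames(
    drift_t,
    drift_d,
    frame_rate: float = 1.0,
    n_markers: int = 2,
    psf_sd: float = 2.0,
    nm_per_px: float = 50.0,
    *,
    img_height: int = 48,
    marker_spacing: int = 40,
    amplitude: float = 8000.0,
    background: float = 200.0,
    seed: int = 0,
):
    """Render surface-bound fiducial markers displaced by the drift path.

    Each frame contains ``n_markers`` Gaussian spots shifted along the image
    x axis (the motility axis) by the drift displacement sampled at frame
    times, with shot (Poisson) pixel noise.

    Returns
    -------
    frames : (n_frames, H, W) uint16 array
    t_frames : (n_frames,) frame times in s
    tracks_nm : (n_frames, n_markers) true marker x displacement in nm
    """
    if nm_per_px <= 0:
        raise SimConfigError("nm_per_px must be > 0")
    if frame_rate <= 0:
        raise SimConfigError("frame_rate must be > 0")
    if n_markers < 1:
        raise SimConfigError("need at least one marker")
    drift_t = np.asarray(drift_t, dtype=float)
    drift_d = np.asarray(drift_d, dtype=float)
    rng = np.random.default_rng(seed)

    t_frames = np.arange(0.0, drift_t[-1] + 0.5 / frame_rate, 1.0 / frame_rate)
    t_frames = t_frames[t_frames <= drift_t[-1] + 1e-9]
    disp_nm = np.interp(t_frames, drift_t, drift_d)
    disp_px = disp_nm / nm_per_px

    H = img_height
    W = marker_spacing * n_markers + marker_spacing // 2
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]
    base_cols = marker_spacing * (np.arange(n_markers) + 0.5)
    base_row = H / 2.0

    frames = np.empty((len(t_frames), H, W), dtype=np.uint16)
    for i, dpx in enumerate(disp_px):
        img = np.full((H, W), background, dtype=float)
        for c0 in base_cols:
            img += amplitude * np.exp(
                -((rr - base_row) ** 2 + (cc - (c0 + dpx)) ** 2) / (2.0 * psf_sd**2)
            )
        noisy = rng.poisson(img)
        frames[i] = np.clip(noisy, 0, 65535).astype(np.uint16)

    tracks_nm = np.tile(disp_nm[:, None], (1, n_markers))
    return frames, t_frames, tracks_nm


def marker_rois(n_markers: int = 2, img_height: int = 48, marker_spacing: int = 40, half: int = 12):
    """Default square ROIs (r0, r1, c0, c1) around each simulated marker."""
    base_cols = marker_spacing * (np.arange(n_markers) + 0.5)
    r0 = int(img_height / 2) - half
    rois = []
    for c in base_cols:
        c0 = int(c) - half
        rois.append((r0, r0 + 2 * half, c0, c0 + 2 * half))
    return rois
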