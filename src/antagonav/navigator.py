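"""Agent-based dual-detector navigation model.

A worm is an active particle with position r, heading theta, and two internal
"confidence" variables integrating sensory input with a single memory
timescale:

    dQ^H/dt = -k1 Q^H + k2_H f_H(C, dC/dt)
    dQ^T/dt = -k1 Q^T + k2_T f_T(C)

The head detector is gradient-sensing (f_H depends on the experienced
concentration change, gated by absolute concentration); the tail detector is
threshold-sensing (f_T peaks at the reference concentration C0 and is
suppressed, down to -1, at high concentration).  Q values are clamped to
[-1, 1]: with k1 = 1/60 and k2 = 1 the raw steady states would be 60 f,
whereas the model requires Q^T -> 1 at C = C0 and Q^T -> -1 as C -> infinity;
clamping reconciles the relaxation dynamics with those limits.

The confidences drive the motor state antagonistically through their
difference:

    gamma = gamma0 exp(-lambda_K (Q^H - Q^T))      (klinokinesis)
    U     = max(0, U0 + U1 (Q^H - Q^T + eta))      (orthokinesis)

Locomotion is run-and-tumble with rotational diffusion; tumble angles come
from a mixture of a uniform circle component and a wrapped Gaussian centred
at pi (reversal-biased).  In addition, a worm with an intact head detector
performs a taxis turn -- heading reset exactly toward the source -- whenever
the local concentration exceeds a threshold while the experienced
concentration is decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .plume_field import FieldSlice2D

__all__ = [
    "ModelParams",
    "WormState",
    "SensorSample",
    "Trajectory",
    "CohortResult",
    "StartRegion",
    "sensory_inputs",
    "update_confidence",
    "motor_state",
    "draw_tumble_angle",
    "step_worm",
    "run_cohort",
    "CONDITIONS",
]

CONDITIONS = ("both", "head_only", "tail_only", "none")


def wrap_angle(theta):
    """Wrap angles to (-pi, pi]."""
    out = np.mod(-np.asarray(theta, float) + np.pi, 2 * np.pi)
    return np.pi - out


@dataclass
class ModelParams:
    """All model constants.  Units: mm, s, rad, mol/m^3.

    gamma0, U0, U1, D_R, k1, k2_H, k2_T carry the published values; lambda_K,
    alpha, sigma, taxis_threshold, and the clamp are exposed model choices
    (see docs/methods.md).  C0 / Cdot0 set the concentration and rate scales
    of the sensory transforms and must match the field the worms navigate.
    """

    gamma0: float = 0.067          # baseline tumble rate (1/s)
    U0: float = 0.064              # baseline speed (mm/s)
    U1: float = 0.03               # speed modulation magnitude (mm/s)
    lambda_K: float = 0.5          # klinokinesis strength (dimensionless)
    D_R: float = 0.02              # rotational diffusivity (rad^2/s)
    k1: float = 1.0 / 60.0         # inverse memory timescale (1/s)
    k2_H: float = 1.0              # head sensitivity (1/s)
    k2_T: float = 1.0              # tail sensitivity (1/s)
    eta_sd: float = 1.0            # speed-noise s.d. (dimensionless)
    eta_mode: Literal["per_step", "constant"] = "per_step"
    alpha: float = 0.3             # uniform weight of the turning kernel
    sigma: float = 0.6             # wrapped-Gaussian width (rad)
    C0: float = 1.0                # reference concentration (mol/m^3)
    Cdot0: float = 1.0             # reference concentration rate (mol/m^3/s)
    taxis_threshold: float | None = None   # default 0.1 * C0
    q_clamp: tuple[float, float] = (-1.0, 1.0)
    confidence_noise: float = 0.05  # relative noise on sensory inputs

    def __post_init__(self) -> None:
        for name in ("gamma0", "U0", "U1", "D_R", "k1", "k2_H", "k2_T", "eta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.C0 <= 0 or self.Cdot0 <= 0:
            raise ValueError("C0 and Cdot0 must be positive")
        if self.q_clamp[0] >= self.q_clamp[1]:
            raise ValueError("q_clamp must be an increasing interval")
        if self.taxis_threshold is None:
            self.taxis_threshold = 0.1 * self.C0


@dataclass
class SensorSample:
    C: float
    Cdot: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.C) < 0):
            raise ValueError("concentration must be nonnegative")


@dataclass
class WormState:
    r: np.ndarray                  # (2,) position, mm
    theta: float                   # heading, wrapped to (-pi, pi]
    Q_H: float = 0.0
    Q_T: float = 0.0
    head_enabled: bool = True
    tail_enabled: bool = True
    last_C: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.theta = float(wrap_angle(self.theta))


@dataclass
class Trajectory:
    """Time-indexed per-worm path record."""

    times: np.ndarray
    positions: np.ndarray          # (n, 2)
    headings: np.ndarray
    speeds: np.ndarray
    Q_H: np.ndarray
    Q_T: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("positions", "headings", "speeds", "Q_H", "Q_T"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class CohortResult:
    """Vectorised cohort record: per-worm channels subsampled in time."""

    condition: str
    seed: int
    times: np.ndarray              # (T,) recorded times
    positions: np.ndarray          # (n, T, 2)
    headings: np.ndarray           # (n, T)
    speeds: np.ndarray             # (n, T)
    Q_H: np.ndarray                # (n, T)
    Q_T: np.ndarray                # (n, T)
    capture_times: np.ndarray      # (n,) nan where never captured
    taxis_counts: np.ndarray       # (n,)
    source_xy: tuple[float, float]
    capture_radius: float
    plate_radius: float
    params: ModelParams

    @property
    def n_worms(self) -> int:
        return self.positions.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            positions=self.positions[i],
            headings=self.headings[i],
            speeds=self.speeds[i],
            Q_H=self.Q_H[i],
            Q_T=self.Q_T[i],
            events={"taxis_count": int(self.taxis_counts[i]),
                    "capture_time": float(self.capture_times[i])},
        )


@dataclass
class StartRegion:
    """Uniform start disc.  Default: radius 5 mm, centred 15 mm from the
    source along the source-to-centre (+x) axis."""

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 5.0


def sensory_inputs(sample: SensorSample, params: ModelParams):
    """Head and tail sensory transforms (f_H, f_T).

    f_H = (Cdot/Cdot0) (1 + tanh(log(C/C0))) / 2 -- the change-rate signal,
    gated up with absolute concentration.  f_T = exp(-(log(C/C0))^2) for
    C <= C0 and 1 - (log(C/C0))^2 above, floored at -1 so the suppressed
    steady confidence respects Q^T -> -1 at high concentration.  C = 0 is
    handled by the log guard (both inputs -> 0).
    """
    C = np.asarray(sample.C, float)
    Cdot = np.asarray(sample.Cdot, float)
    f_H, f_T = _sensory_arrays(C, Cdot, params)
    if np.ndim(sample.C) == 0:
        return float(f_H), float(f_T)
    return f_H, f_T


def update_confidence(Q, f, k1: float, k2: float, dt: float,
                      clamp: tuple[float, float] = (-1.0, 1.0)):
    """Explicit Euler step of dQ/dt = -k1 Q + k2 f, then clamp."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * k1 >= 1:
        raise ValueError("dt * k1 must be < 1 for a stable explicit step")
    return np.clip(Q + dt * (-k1 * Q + k2 * f), clamp[0], clamp[1])


def motor_state(Q_H, Q_T, eta, params: ModelParams):
    """Map the confidence contrast to (speed U, tumble rate gamma)."""
    dq = np.asarray(Q_H, float) - np.asarray(Q_T, float)
    gamma = params.gamma0 * np.exp(-params.lambda_K * dq)
    U = np.maximum(0.0, params.U0 + params.U1 * (dq + eta))
    return U, gamma


def draw_tumble_angle(rng: np.random.Generator, alpha: float, sigma: float,
                      size=None):
    """Tumble heading increment: mixture of a uniform circle component
    (weight alpha) and a wrapped Gaussian centred at pi (reversal bias),
    wrapped to (-pi, pi]."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = 1 if size is None else int(size)
    use_uniform = rng.random(n) < alpha
    uni = rng.uniform(-np.pi, np.pi, n)
    gauss = np.pi + sigma * rng.standard_normal(n)
    out = wrap_angle(np.where(use_uniform, uni, gauss))
    return float(out[0]) if size is None else out


def _reflect_at_wall(r: np.ndarray, theta: np.ndarray, radius: float):
    """Specular reflection at the circular rim: fold the radial overshoot
    back inside and reflect the heading about the local tangent."""
    d = np.hypot(r[:, 0], r[:, 1])
    out = d > radius
    if np.any(out):
        phi = np.arctan2(r[out, 1], r[out, 0])
        d_new = np.maximum(2 * radius - d[out], 0.0)
        r[out, 0] = d_new * np.cos(phi)
        r[out, 1] = d_new * np.sin(phi)
        theta[out] = wrap_angle(2 * phi + np.pi - theta[out])
    return r, theta


def _step_arrays(r, theta, Q_H, Q_T, last_C, active, slc, t, dt, params,
                 head_enabled, tail_enabled, source_xy, rng):
    """Advance all active worms by one time step (in place); returns the
    taxis mask.  Draw order is fixed so runs are bit-reproducible."""
    n = r.shape[0]
    # fixed-sequence draws (full size regardless of masks)
    rot = rng.standard_normal(n)
    u_tumble = rng.random(n)
    d_tumble = draw_tumble_angle(rng, params.alpha, params.sigma, size=n)
    eta = rng.standard_normal(n) * params.eta_sd if params.eta_mode == "per_step" \
        else np.full(n, params.eta_sd)
    xi_h = rng.standard_normal(n)
    xi_t = rng.standard_normal(n)

    C = np.asarray(slc.sample_C(r[:, 0], r[:, 1], t), float)
    Cdot = (C - last_C) / dt

    f_H, f_T = _sensory_arrays(C, Cdot, params)
    if params.confidence_noise > 0:
        f_H = f_H * (1 + params.confidence_noise * xi_h)
        f_T = f_T * (1 + params.confidence_noise * xi_t)

    lo, hi = params.q_clamp
    if head_enabled:
        Q_H_new = np.clip(Q_H + dt * (-params.k1 * Q_H + params.k2_H * f_H), lo, hi)
    else:
        Q_H_new = np.zeros(n)
    if tail_enabled:
        Q_T_new = np.clip(Q_T + dt * (-params.k1 * Q_T + params.k2_T * f_T), lo, hi)
    else:
        Q_T_new = np.zeros(n)
    Q_H[active] = Q_H_new[active]
    Q_T[active] = Q_T_new[active]

    U, gamma = motor_state(Q_H, Q_T, eta, params)

    theta_new = theta + np.sqrt(2 * params.D_R * dt) * rot
    tumble = u_tumble < -np.expm1(-gamma * dt)
    theta_new = np.where(tumble, theta_new + d_tumble, theta_new)

    taxis = np.zeros(n, bool)
    if head_enabled:
        taxis = (C > params.taxis_threshold) & (Cdot < 0) & active
        if np.any(taxis):
            theta_new = np.where(
                taxis,
                np.arctan2(source_xy[1] - r[:, 1], source_xy[0] - r[:, 0]),
                theta_new,
            )
    theta_new = wrap_angle(theta_new)

    r_new = r + (U * dt)[:, None] * np.stack(
        [np.cos(theta_new), np.sin(theta_new)], axis=1
    )
    r_new, theta_new = _reflect_at_wall(r_new, theta_new, slc.radius)

    r[active] = r_new[active]
    theta[active] = theta_new[active]
    last_C[active] = C[active]
    return taxis, U


def _sensory_arrays(C, Cdot, params: ModelParams):
    with np.errstate(divide="ignore"):
        logc = np.log(np.where(C > 0, C, 1.0) / params.C0)
    f_H = np.where(C > 0, (Cdot / params.Cdot0) * (1 + np.tanh(logc)) / 2, 0.0)
    f_T = np.where(
        C <= params.C0,
        np.exp(-np.square(logc)),
        np.maximum(1 - np.square(logc), -1.0),
    )
    f_T = np.where(C > 0, f_T, 0.0)
    return f_H, f_T


def step_worm(state: WormState, slc: FieldSlice2D, t: float, dt: float,
              params: ModelParams, rng: np.random.Generator,
              source_xy: tuple[float, float] | None = None) -> WormState:
    """Advance a single worm one step; scalar wrapper over the vectorised
    kernel (the cohort runner shares the same code path)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.hypot(*state.r) > slc.radius:
        raise ValueError("worm outside the plate")
    if source_xy is None:
        source_xy = slc.source_xy
    r = state.r[None, :].copy()
    theta = np.array([state.theta])
    Q_H = np.array([state.Q_H])
    Q_T = np.array([state.Q_T])
    last_C = np.array([state.last_C])
    active = np.array([True])
    _step_arrays(r, theta, Q_H, Q_T, last_C, active, slc, t, dt, params,
                 state.head_enabled, state.tail_enabled, source_xy, rng)
    return WormState(
        r=r[0], theta=float(theta[0]), Q_H=float(Q_H[0]), Q_T=float(Q_T[0]),
        head_enabled=state.head_enabled, tail_enabled=state.tail_enabled,
        last_C=float(last_C[0]),
    )


def run_cohort(
    n_worms: int,
    condition: str,
    slc: FieldSlice2D,
    duration: float,
    dt: float = 0.1,
    init: StartRegion | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
    source_xy: tuple[float, float] | None = None,
    capture_radius: float = 3.0,
    record_every: float = 10.0,
) -> CohortResult:
    """Simulate a cohort of worms under one detector condition.

    condition: 'both', 'head_only', 'tail_only', or 'none'; the disabled
    detector's confidence is frozen at 0 and head-disabled worms never
    perform taxis turns.  A worm within ``capture_radius`` of the source is
    counted as having found it and frozen in place (endpoint-assay
    semantics).  Channels are recorded every ``record_every`` seconds.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    params = params if params is not None else ModelParams()
    init = init if init is not None else _default_start(slc, source_xy)
    if source_xy is None:
        source_xy = slc.source_xy
    if np.hypot(*init.center) + init.radius > slc.radius:
        raise ValueError("start region extends outside the plate")

    head_enabled = condition in ("both", "head_only")
    tail_enabled = condition in ("both", "tail_only")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, CONDITIONS.index(condition)])
    )

    # uniform positions in the start disc, uniform random headings
    u = rng.random(n_worms)
    ang = rng.uniform(-np.pi, np.pi, n_worms)
    rad = init.radius * np.sqrt(u)
    r = np.stack([init.center[0] + rad * np.cos(ang),
                  init.center[1] + rad * np.sin(ang)], axis=1)
    theta = rng.uniform(-np.pi, np.pi, n_worms)
    Q_H = np.zeros(n_worms)
    Q_T = np.zeros(n_worms)
    last_C = np.asarray(slc.sample_C(r[:, 0], r[:, 1], 0.0), float).copy()
    if last_C.ndim == 0:
        last_C = np.full(n_worms, float(last_C))
    capture_times = np.full(n_worms, np.nan)
    taxis_counts = np.zeros(n_worms, int)

    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    rec_idx = list(range(0, n_steps + 1, rec_stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    T = len(rec_idx)
    pos_rec = np.empty((n_worms, T, 2))
    th_rec = np.empty((n_worms, T))
    sp_rec = np.zeros((n_worms, T))
    qh_rec = np.empty((n_worms, T))
    qt_rec = np.empty((n_worms, T))
    times_rec = np.array(rec_idx, float) * dt

    sx, sy = source_xy
    captured = np.hypot(r[:, 0] - sx, r[:, 1] - sy) <= capture_radius
    capture_times[captured] = 0.0

    rec_ptr = 0
    U_last = np.zeros(n_worms)
    for step in range(n_steps + 1):
        if rec_ptr < T and step == rec_idx[rec_ptr]:
            pos_rec[:, rec_ptr] = r
            th_rec[:, rec_ptr] = theta
            sp_rec[:, rec_ptr] = U_last
            qh_rec[:, rec_ptr] = Q_H
            qt_rec[:, rec_ptr] = Q_T
            rec_ptr += 1
        if step == n_steps:
            break
        t = step * dt
        active = ~captured
        taxis, U_last = _step_arrays(
            r, theta, Q_H, Q_T, last_C, active, slc, t, dt, params,
            head_enabled, tail_enabled, source_xy, rng,
        )
        taxis_counts += taxis & active
        newly = active & (np.hypot(r[:, 0] - sx, r[:, 1] - sy) <= capture_radius)
        capture_times[newly] = (step + 1) * dt
        captured |= newly

    return CohortResult(
        condition=condition,
        seed=seed,
        times=times_rec,
        positions=pos_rec,
        headings=th_rec,
        speeds=sp_rec,
        Q_H=qh_rec,
        Q_T=qt_rec,
        capture_times=capture_times,
        taxis_counts=taxis_counts,
        source_xy=tuple(source_xy),
        capture_radius=capture_radius,
        plate_radius=slc.radius,
        params=params,
    )


def _default_start(slc: FieldSlice2D,
                   source_xy: tuple[float, float] | None) -> StartRegion:
    sx, sy = source_xy if source_xy is not None else slc.source_xy
    d = np.hypot(sx, sy)
    if d > 1e-9:
        # 15 mm from the source along the source -> plate-centre direction
        ux, uy = -sx / d, -sy / d
    else:
        ux, uy = 1.0, 0.0
    return StartRegion(center=(sx + 15.0 * ux, sy + 15.0 * uy), radius=5.0)
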