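"""Synthetic inputs emulating the study's raw data products.

Every generator is seeded and embeds its generative parameters, so each
downstream analysis has at least one input whose ground truth is known in
closed form:

* two-channel calcium traces with a fast (sustained, stimulus-locked) and a
  slow (delayed-onset, reduced-amplitude) responder class,
* stimulation-locked speed traces for spectral analysis,
* circuit triplets (two regressor neurons plus a linearly composed command
  neuron trace),
* multinomial endpoint-assay counts for chemotaxis indices,
* analytic toy concentration slices (uniform / linear / gaussian hill) with
  exact samplers, used as oracles for the navigator and the along-body
  contrast statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium_metrics import CalciumTrace
from .traj_metrics import AssayCounts, SpeedSeries

__all__ = [
    "ResponderSpec",
    "StimProtocol",
    "AnalyticFieldSlice",
    "gen_calcium_traces",
    "gen_periodic_speed",
    "gen_circuit_traces",
    "gen_endpoint_counts",
    "gen_toy_field",
]


@dataclass
class ResponderSpec:
    """Fast/slow responder mixture for tail-detector calcium traces.

    Defaults carry the reported population structure: 62.5% fast responders;
    slow responders start 2.5 min late with a 40% reduced amplitude.
    """

    fast_fraction: float = 0.625
    slow_delay: float = 150.0          # s
    slow_amplitude_factor: float = 0.6
    amplitude: float = 1.0             # plateau dR/R0 of a fast responder
    rise_time: float = 10.0            # s, linear onset ramp
    plateau_hold: float = 120.0        # s at full amplitude before decay
    decay_time: float = 600.0          # s, slow plateau decay
    noise_sd: float = 0.02             # multiplicative channel noise
    baseline_ratio: float = 2.0        # quiescent GCaMP/reference ratio

    def __post_init__(self) -> None:
        if not 0 <= self.fast_fraction <= 1:
            raise ValueError("fast_fraction must lie in [0, 1]")
        if not 0 < self.slow_amplitude_factor <= 1:
            raise ValueError("slow_amplitude_factor must lie in (0, 1]")


@dataclass
class StimProtocol:
    """Periodic stimulation: ``on_duration`` s on, ``off_duration`` s off,
    repeated ``n_cycles`` times after ``pre_baseline`` s of quiet."""

    on_duration: float
    off_duration: float
    n_cycles: int = 8
    pre_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("on and off durations must be positive")

    @property
    def period(self) -> float:
        return self.on_duration + self.off_duration

    @property
    def duration(self) -> float:
        return self.pre_baseline + self.n_cycles * self.period

    def epochs(self) -> list[tuple[float, float]]:
        return [
            (self.pre_baseline + k * self.period,
             self.pre_baseline + k * self.period + self.on_duration)
            for k in range(self.n_cycles)
        ]

    def on_mask(self, times: np.ndarray) -> np.ndarray:
        phase = times - self.pre_baseline
        in_train = (phase >= 0) & (phase < self.n_cycles * self.period)
        return in_train & (np.mod(phase, self.period) < self.on_duration)


def _response_shape(times, onset, amplitude, spec: ResponderSpec):
    """Linear ramp to full amplitude over ``rise_time``, held for
    ``plateau_hold``, then slow exponential decay.  The peak equals
    ``amplitude`` exactly (noise-free ground truth for recovery tests)."""
    d = times - onset
    ramp = np.clip(d / spec.rise_time, 0.0, 1.0)
    decay = np.exp(-np.maximum(d - spec.rise_time - spec.plateau_hold, 0.0)
                   / spec.decay_time)
    return amplitude * ramp * decay


def gen_calcium_traces(
    n: int,
    spec: ResponderSpec | None = None,
    sampling_rate: float = 2.0,
    duration: float = 570.0,
    stim_onset: float = 30.0,
    seed: int = 0,
) -> tuple[list[CalciumTrace], np.ndarray]:
    """Two-channel traces with Bernoulli(fast_fraction) class assignment.

    Returns (traces, labels) with labels 'fast'/'slow'.  At noise_sd = 0 a
    fast responder's plateau equals ``spec.amplitude`` exactly and a slow
    responder's peak is ``slow_amplitude_factor`` times the fast peak.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec if spec is not None else ResponderSpec()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, 1.0 / sampling_rate)
    labels = np.where(rng.random(n) < spec.fast_fraction, "fast", "slow")
    traces = []
    for i in range(n):
        fast = labels[i] == "fast"
        onset = stim_onset if fast else stim_onset + spec.slow_delay
        amp = spec.amplitude if fast else spec.amplitude * spec.slow_amplitude_factor
        drr = _response_shape(times, onset, amp, spec)
        reference = np.full_like(times, 1.0)
        gcamp = spec.baseline_ratio * (1 + drr) * reference
        if spec.noise_sd > 0:
            gcamp = gcamp * (1 + spec.noise_sd * rng.standard_normal(times.size))
            reference = reference * (1 + spec.noise_sd * rng.standard_normal(times.size))
        traces.append(
            CalciumTrace(
                times=times.copy(),
                gcamp=np.maximum(gcamp, 1e-9),
                reference=np.maximum(reference, 1e-9),
                stim_onset=stim_onset,
                epochs={"pre": (0.0, stim_onset),
                        "stimulus": (stim_onset, duration)},
                meta={"label": str(labels[i]), "onset": onset, "amplitude": amp,
                      "spec": spec.__dict__.copy(), "seed": seed},
            )
        )
    return traces, labels


def gen_periodic_speed(
    protocol: StimProtocol,
    response_gain: float = 0.5,
    noise_sd: float = 0.1,
    sampling_rate: float = 2.0,
    baseline_speed: float = 0.064,
    seed: int = 0,
) -> SpeedSeries:
    """Stimulation-locked speed trace: baseline plus an additive elevation
    of ``response_gain * baseline_speed`` during light-on epochs, plus
    Gaussian noise of s.d. ``noise_sd * baseline_speed``."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, protocol.duration, 1.0 / sampling_rate)
    values = baseline_speed * (
        1.0
        + response_gain * protocol.on_mask(times)
        + noise_sd * rng.standard_normal(times.size)
    )
    return SpeedSeries(
        times=times,
        values=np.maximum(values, 0.0),
        sampling_rate=sampling_rate,
        stimulation_epochs=protocol.epochs(),
        meta={"protocol": protocol.__dict__.copy(), "response_gain": response_gain,
              "noise_sd": noise_sd, "baseline_speed": baseline_speed, "seed": seed},
    )


def gen_circuit_traces(
    coefficients: tuple[float, float, float] = (-0.7, 0.1, -0.2),
    n_samples: int = 600,
    noise_sd: float = 0.05,
    sampling_rate: float = 2.0,
    smooth: float = 10.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Regressor traces (AWA, PHD) as independent smoothed random walks and
    a command-neuron trace AVA = a*AWA + b*PHD + c + noise.

    Default coefficients are the published head/tail -> command decomposition
    (-0.7, 0.1, -0.2), used as generative ground truth for recovery tests.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    a, b, c = coefficients
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter1d

    def walk():
        w = np.cumsum(rng.standard_normal(n_samples))
        w = gaussian_filter1d(w, smooth, mode="nearest")
        w = w - w.min()
        rng_span = w.max()
        return w / rng_span if rng_span > 0 else w

    awa = walk()
    phd = walk()
    ava = a * awa + b * phd + c
    if noise_sd > 0:
        ava = ava + noise_sd * rng.standard_normal(n_samples)
    times = np.arange(n_samples) / sampling_rate
    return {
        "times": times,
        "AWA": awa,
        "PHD": phd,
        "AVA": ava,
        "meta": {"coefficients": (a, b, c), "noise_sd": noise_sd, "seed": seed},
    }


def gen_endpoint_counts(
    n_worms: int = 20,
    p_test: float = 0.6,
    p_control: float = 0.1,
    n_trials: int = 10,
    assay_type: str = "type2",
    seed: int = 0,
) -> list[AssayCounts]:
    """Multinomial endpoint counts (test spot, control spot, neither) per
    trial; defaults mirror the 20-worms-per-trial, 10-trial assay design."""
    if p_test + p_control > 1 + 1e-12:
        raise ValueError("p_test + p_control must be <= 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(
        n_worms, [p_test, p_control, 1.0 - p_test - p_control], size=n_trials
    )
    return [
        AssayCounts(E=int(e), C=int(c), N=int(nn), assay_type=assay_type)
        for e, c, nn in draws
    ]


class AnalyticFieldSlice:
    """Closed-form 2-D concentration slice with exact samplers.

    Drop-in replacement for :class:`antagonav.plume_field.FieldSlice2D`
    wherever only ``sample_C`` / ``sample_dCdt`` / ``radius`` / ``source_xy``
    are consumed; used as an oracle for navigator and contrast tests.

    kinds
    -----
    uniform:        C = level (optionally growing at ``rate`` per second)
    linear:         C = offset + slope_x * x + slope_y * y
    gaussian_hill:  C = peak * exp(-((x-cx)^2+(y-cy)^2)/(2 width^2))
    """

    def __init__(self, kind: str, radius: float = 40.0,
                 source_xy: tuple[float, float] = (0.0, 0.0),
                 times: np.ndarray | None = None, **params):
        if kind not in ("uniform", "linear", "gaussian_hill"):
            raise ValueError(f"unknown toy field kind {kind!r}")
        self.kind = kind
        self.radius = float(radius)
        self.source_xy = tuple(source_xy)
        self.params = params
        self.times = times if times is not None else np.array([0.0, np.inf])
        self.plane_z = params.get("plane_z", -0.5)

    def sample_C(self, xq, yq, t: float):
        x = np.asarray(xq, float)
        y = np.asarray(yq, float)
        p = self.params
        if self.kind == "uniform":
            c = np.full_like(x, p.get("level", 1.0)) + p.get("rate", 0.0) * t
        elif self.kind == "linear":
            c = (p.get("offset", 1.0) + p.get("slope_x", 0.0) * x
                 + p.get("slope_y", 0.0) * y)
        else:
            cx, cy = p.get("center", self.source_xy)
            w = p.get("width", 10.0)
            c = p.get("peak", 1.0) * np.exp(
                -((x - cx) ** 2 + (y - cy) ** 2) / (2 * w**2)
            )
        return np.maximum(c, 0.0)

    def sample_dCdt(self, xq, yq, t: float):
        x = np.asarray(xq, float)
        if self.kind == "uniform":
            return np.full_like(x, self.params.get("rate", 0.0))
        return np.zeros_like(x)

    def gradient(self, xq, yq, t: float = 0.0):
        """Exact spatial gradient (oracle only)."""
        x = np.asarray(xq, float)
        y = np.asarray(yq, float)
        p = self.params
        if self.kind == "uniform":
            return np.zeros_like(x), np.zeros_like(y)
        if self.kind == "linear":
            return (np.full_like(x, p.get("slope_x", 0.0)),
                    np.full_like(y, p.get("slope_y", 0.0)))
        cx, cy = p.get("center", self.source_xy)
        w = p.get("width", 10.0)
        c = self.sample_C(x, y, t)
        return -(x - cx) / w**2 * c, -(y - cy) / w**2 * c


def gen_toy_field(kind: str, params: dict | None = None,
                  radius: float = 40.0,
                  source_xy: tuple[float, float] = (0.0, 0.0)) -> AnalyticFieldSlice:
    """Build an analytic toy slice; see :class:`AnalyticFieldSlice`."""
    return AnalyticFieldSlice(kind, radius=radius, source_xy=source_xy,
                              **(params or {}))
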