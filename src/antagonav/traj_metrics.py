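"""Trajectory-level analytics.

Speed series and their stimulation-locked power spectra, 2-s-window
behavioural motif classification (four- and six-motif schemes), endpoint
chemotaxis indices, and cohort summaries (success curves, mean horizontal
position <x>, per-worm maximum source distance d_max).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .navigator import CohortResult, Trajectory

__all__ = [
    "SpeedSeries",
    "MotifSequence",
    "AssayCounts",
    "CohortSummary",
    "MOTIF_LABELS",
    "speed_series",
    "power_spectrum",
    "classify_motifs",
    "chemotaxis_index",
    "cohort_summary",
]

MOTIF_LABELS = ("forward", "backward", "fwd_bwd", "bwd_fwd",
                "high_freq", "self_exploratory")


@dataclass
class SpeedSeries:
    """Uniformly sampled speed trace.  ``values`` is the speed magnitude
    (mm/s) or, for motif classification, a signed along-body velocity."""

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float
    stimulation_epochs: list = field(default_factory=list)
    signed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("sampling must be uniform (resample first)")
        if not self.signed and np.any(self.values < -1e-12):
            raise ValueError("magnitude channel must be nonnegative")


@dataclass
class MotifSequence:
    window_starts: np.ndarray
    labels: list
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in ("four", "six"):
            raise ValueError("scheme must be 'four' or 'six'")


@dataclass
class AssayCounts:
    """Endpoint counts at the test spot (E), control spot (C), neither (N)."""

    E: int
    C: int
    N: int
    assay_type: str = "type2"

    def __post_init__(self) -> None:
        if min(self.E, self.C, self.N) < 0:
            raise ValueError("counts must be nonnegative")
        if self.assay_type not in ("type1", "type2"):
            raise ValueError("assay_type must be 'type1' or 'type2'")


@dataclass
class CohortSummary:
    times: np.ndarray
    success_curve: np.ndarray
    mean_x: float
    d_max: np.ndarray
    d_max_mean: float
    d_max_var: float
    d_max_hist: tuple[np.ndarray, np.ndarray]


def speed_series(traj: Trajectory, smoothing_window: float = 0.0) -> SpeedSeries:
    """Centred finite-difference speed magnitude, optionally box-smoothed.

    ``smoothing_window`` is in seconds; 0 disables smoothing.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least two samples to differentiate")
    times = np.asarray(traj.times, float)
    pos = np.asarray(traj.positions, float)
    vx = np.gradient(pos[:, 0], times)
    vy = np.gradient(pos[:, 1], times)
    v = np.hypot(vx, vy)
    dt = times[1] - times[0]
    if smoothing_window > 0:
        w = max(1, int(round(smoothing_window / dt)))
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    return SpeedSeries(times=times, values=v, sampling_rate=1.0 / dt)


def power_spectrum(series: SpeedSeries, detrend: bool = True,
                   background_halfwidth: int = 20, peak_exclusion: int = 2):
    """One-sided periodogram with the DC bin excluded from the peak search.

    Returns (frequencies, power, dominant_peak, peak_strength).
    ``peak_strength`` is the square root of the peak power over the median
    power in a local background window of ``background_halfwidth`` bins
    around the peak (excluding the ``peak_exclusion`` bins nearest to it) --
    an amplitude-scale operationalisation of the amplitude-and-sharpness of
    the spectral peak, so that doubling a response's modulation amplitude
    approximately doubles the reported strength.  A warning is raised when
    the record is shorter than five cycles of the dominant period.
    """
    freqs, power = signal.periodogram(
        series.values,
        fs=series.sampling_rate,
        detrend="linear" if detrend else False,
        window="boxcar",
    )
    pos = freqs > 0
    freqs_pos, power_pos = freqs[pos], power[pos]
    k = int(np.argmax(power_pos))
    dominant = float(freqs_pos[k])

    lo = max(0, k - background_halfwidth)
    hi = min(power_pos.size, k + background_halfwidth + 1)
    idx = np.arange(lo, hi)
    idx = idx[np.abs(idx - k) > peak_exclusion]
    background = float(np.median(power_pos[idx])) if idx.size else np.nan
    strength = float(np.sqrt(power_pos[k] / background)) if background > 0 else np.inf

    duration = series.times[-1] - series.times[0]
    if dominant > 0 and duration < 5 / dominant:
        warnings.warn("record shorter than 5 cycles of the dominant period; "
                      "frequency resolution is marginal", stacklevel=2)
    return freqs_pos, power_pos, dominant, strength


def _window_label(signs: np.ndarray, scheme: str,
                  self_exploring: bool) -> str:
    """Label one 2-s window from the signs of its signed-velocity samples.

    Direction changes are sign changes between consecutive nonzero-signed
    samples.  >2 changes -> high_freq (six-scheme); otherwise the label is
    set by the (first, last) sign pair -- the documented tie rule, which also
    resolves exactly-2-change windows by their net start/end direction.
    """
    if scheme == "six" and self_exploring:
        return "self_exploratory"
    nz = signs[signs != 0]
    if nz.size == 0:
        return "forward"  # degenerate all-zero window: treated as forward
    changes = int(np.count_nonzero(np.diff(nz) != 0))
    if changes > 2 and scheme == "six":
        return "high_freq"
    first, last = nz[0], nz[-1]
    if first > 0 and last > 0:
        return "forward"
    if first < 0 and last < 0:
        return "backward"
    return "fwd_bwd" if first > 0 else "bwd_fwd"


def classify_motifs(signed_velocity: SpeedSeries, window: float = 2.0,
                    scheme: str = "six",
                    proximity_channel: np.ndarray | None = None,
                    proximity_fraction: float = 0.5) -> MotifSequence:
    """Classify contiguous ``window``-second segments of a signed velocity.

    four-scheme: forward / backward / fwd_bwd / bwd_fwd.
    six-scheme additionally emits high_freq (>2 direction changes in the
    window) and self_exploratory (sustained self-proximity flag for more
    than ``proximity_fraction`` of the window; requires
    ``proximity_channel``).
    """
    if scheme not in ("four", "six"):
        raise ValueError("scheme must be 'four' or 'six'")
    if not signed_velocity.signed:
        raise ValueError("motif classification needs a signed velocity channel")
    six_with_proximity = scheme == "six" and proximity_channel is not None
    if scheme == "six" and proximity_channel is None:
        warnings.warn("six-scheme without a proximity channel: "
                      "self_exploratory cannot be emitted (five usable labels)",
                      stacklevel=2)
    v = signed_velocity.values
    t = signed_velocity.times
    n_per = max(1, int(round(window * signed_velocity.sampling_rate)))
    n_win = v.size // n_per
    starts = t[0] + np.arange(n_win) * window
    labels = []
    for w in range(n_win):
        sl = slice(w * n_per, (w + 1) * n_per)
        self_exploring = bool(
            six_with_proximity
            and np.mean(np.asarray(proximity_channel[sl], bool)) > proximity_fraction
        )
        labels.append(_window_label(np.sign(v[sl]), scheme, self_exploring))
    return MotifSequence(window_starts=starts, labels=labels, scheme=scheme)


def chemotaxis_index(counts: AssayCounts) -> float:
    """Endpoint chemotaxis index.

    type2 (test + control spots): (E - C) / (E + C + N).
    type1 (no control spot):       E / (E + C + N).
    """
    total = counts.E + counts.C + counts.N
    if total == 0:
        raise ValueError("undefined index: zero total count")
    if counts.assay_type == "type1":
        return counts.E / total
    return (counts.E - counts.C) / total


def cohort_summary(result: CohortResult,
                   source_xy: tuple[float, float] | None = None,
                   capture_radius: float | None = None,
                   origin: tuple[float, float] = (0.0, 0.0),
                   hist_bins: int = 30) -> CohortSummary:
    """Success curve, mean horizontal position <x>, and d_max distribution.

    The x axis points from the source toward ``origin`` (the plate centre);
    <x> is the per-worm time-average of the projected position, then the
    cohort mean.  d_max is each worm's maximum recorded distance from the
    source; the success curve is the fraction of worms whose first-capture
    time is <= t.
    """
    if result.n_worms == 0:
        raise ValueError("empty cohort")
    source_xy = source_xy if source_xy is not None else result.source_xy
    sx, sy = source_xy
    ex, ey = origin[0] - sx, origin[1] - sy
    norm = np.hypot(ex, ey)
    if norm < 1e-12:
        ex, ey = 1.0, 0.0
    else:
        ex, ey = ex / norm, ey / norm

    pos = result.positions  # (n, T, 2)
    x_proj = pos[..., 0] * ex + pos[..., 1] * ey
    mean_x = float(np.mean(np.mean(x_proj, axis=1)))

    d = np.hypot(pos[..., 0] - sx, pos[..., 1] - sy)
    d_max = d.max(axis=1)

    t_grid = result.times
    ct = result.capture_times
    success = np.array([
        np.count_nonzero(~np.isnan(ct) & (ct <= t)) for t in t_grid
    ]) / result.n_worms

    counts, edges = np.histogram(d_max, bins=hist_bins)
    return CohortSummary(
        times=t_grid,
        success_curve=success,
        mean_x=mean_x,
        d_max=d_max,
        d_max_mean=float(d_max.mean()),
        d_max_var=float(d_max.var()),
        d_max_hist=(counts, edges),
    )
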