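"""Calcium-trace computations.

Two-channel ratio dR/R0 with Savitzky-Golay filtering, sign-restricted AUC
dose analysis, Pearson correlation screening, unit-interval normalisation,
and the linear head/tail -> command-neuron decomposition (with the
dual-stimulation vs head+tail sum comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "CalciumTrace",
    "RatioTrace",
    "AUCResult",
    "CircuitFit",
    "ratio_trace",
    "auc_response",
    "correlation_screen",
    "normalize_unit_interval",
    "fit_linear_combination",
    "dual_vs_sum",
]


@dataclass
class CalciumTrace:
    """Raw two-channel fluorescence: GCaMP over a reference fluorophore
    (mNeptune/RFP), with stimulation epoch markers."""

    times: np.ndarray
    gcamp: np.ndarray
    reference: np.ndarray
    stim_onset: float
    epochs: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.gcamp = np.asarray(self.gcamp, float)
        self.reference = np.asarray(self.reference, float)
        if not (self.times.size == self.gcamp.size == self.reference.size):
            raise ValueError("channels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.gcamp <= 0) or np.any(self.reference <= 0):
            raise ValueError("fluorescence channels must be positive")


@dataclass
class RatioTrace:
    times: np.ndarray
    R: np.ndarray
    R0: float
    dRR0: np.ndarray

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("baseline ratio R0 must be positive")


@dataclass
class AUCResult:
    baseline: float
    auc: float
    mode: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mode not in ("suppression", "excitation"):
            raise ValueError("mode must be 'suppression' or 'excitation'")


@dataclass
class CircuitFit:
    names: tuple
    coefficients: np.ndarray
    intercept: float
    residual_rms: float


def ratio_trace(trace: CalciumTrace, filter_order: int = 1,
                filter_length: int = 13,
                baseline_epoch: tuple[float, float] | None = None) -> RatioTrace:
    """Filtered ratio R = F(GCaMP)/F(reference) and dR/R0.

    Each channel is Savitzky-Golay filtered (defaults: polynomial order 1,
    window length 13; mirror-padded edges), the ratio is taken pointwise,
    and R0 is the mean R over the quiescent baseline epoch (default: the
    labelled 'pre' epoch, else everything before stimulus onset).
    """
    if filter_length % 2 == 0 or filter_length <= filter_order:
        raise ValueError("filter_length must be odd and > filter_order")
    if baseline_epoch is None:
        baseline_epoch = trace.epochs.get("pre", (trace.times[0], trace.stim_onset))
    t0, t1 = baseline_epoch
    in_base = (trace.times >= t0) & (trace.times < t1)
    if not np.any(in_base):
        raise ValueError("baseline epoch contains no samples")

    g = savgol_filter(trace.gcamp, filter_length, filter_order, mode="mirror")
    ref = savgol_filter(trace.reference, filter_length, filter_order, mode="mirror")
    if np.any(ref <= 0):
        raise ValueError("filtered reference channel is nonpositive")
    R = g / ref
    R0 = float(R[in_base].mean())
    return RatioTrace(times=trace.times, R=R, R0=R0, dRR0=(R - R0) / R0)


def auc_response(times, values, stim_time: float,
                 baseline_window: float = 180.0,
                 integration_window: float = 120.0,
                 mode: str = "suppression",
                 baseline: float | None = None) -> AUCResult:
    """Sign-restricted area under the curve after stimulation.

    The baseline is the mean over [stim - baseline_window, stim) unless
    supplied explicitly (a titration series uses the most-dilute condition's
    baseline for the whole series).  The baseline-subtracted signal is then
    integrated (trapezoid) over [stim, stim + integration_window], keeping
    only sub-baseline intervals in suppression mode (AUC <= 0) or
    supra-baseline intervals in excitation mode (AUC >= 0).
    """
    if mode not in ("suppression", "excitation"):
        raise ValueError("mode must be 'suppression' or 'excitation'")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if baseline is None:
        if times[0] > stim_time - baseline_window + 1e-9:
            raise ValueError("trace does not cover the baseline window")
        pre = (times >= stim_time - baseline_window) & (times < stim_time)
        baseline = float(values[pre].mean())
    if times[-1] < stim_time + integration_window - 1e-9:
        raise ValueError("trace does not cover the integration window")

    post = (times >= stim_time) & (times <= stim_time + integration_window)
    dev = values[post] - baseline
    dev = np.minimum(dev, 0.0) if mode == "suppression" else np.maximum(dev, 0.0)
    auc = float(np.trapezoid(dev, times[post]))
    return AUCResult(baseline=baseline, auc=auc, mode=mode,
                     window=(stim_time, stim_time + integration_window))


def correlation_screen(candidates: dict, reference, cutoff: float = 0.55):
    """Pearson correlation of each candidate series with the reference.

    Returns (selected_names, table) where table maps name -> r.  Selection
    is strict (r > cutoff).  Zero-variance candidates are excluded with a
    warning and appear in the table as nan.
    """
    reference = np.asarray(reference, float)
    selected, table = [], {}
    for name, series in candidates.items():
        series = np.asarray(series, float)
        if series.size != reference.size:
            raise ValueError(f"candidate {name!r} length mismatch")
        if np.std(series) == 0 or np.std(reference) == 0:
            warnings.warn(f"zero-variance series {name!r} excluded", stacklevel=2)
            table[name] = np.nan
            continue
        r = float(np.corrcoef(series, reference)[0, 1])
        table[name] = r
        if r > cutoff:
            selected.append(name)
    return selected, table


def normalize_unit_interval(series):
    """Map a series affinely onto [0, 1]; a constant series returns all
    zeros with a degeneracy flag.  Returns (normalised, degenerate)."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def fit_linear_combination(target, regressors: dict) -> CircuitFit:
    """Ordinary least squares of target on named regressors plus intercept.

    Implements the command-neuron decomposition (e.g. AVA activity as a
    linear combination of AWA and PHD activity) over a user-chosen window.
    """
    target = np.asarray(target, float)
    names = tuple(regressors.keys())
    X = np.column_stack([np.asarray(regressors[k], float) for k in names])
    if X.shape[0] != target.size:
        raise ValueError("regressor length mismatch")
    if target.size < X.shape[1] + 1 + 3:
        raise ValueError("need at least 3 more samples than coefficients")
    A = np.column_stack([X, np.ones(target.size)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (collinear regressors)")
    beta, *_ = np.linalg.lstsq(A, target, rcond=None)
    resid = target - A @ beta
    return CircuitFit(
        names=names,
        coefficients=beta[:-1],
        intercept=float(beta[-1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def dual_vs_sum(auc_head: AUCResult, auc_tail: AUCResult,
                auc_dual: AUCResult) -> dict:
    """Compare dual-stimulation AUC with the sum of single-side AUCs.

    Tests the additive-integration hypothesis: if command-neuron responses
    combine head and tail drives linearly, AUC(dual) ~ AUC(head) + AUC(tail).
    """
    if not (auc_head.mode == auc_tail.mode == auc_dual.mode):
        raise ValueError("AUC modes do not match")
    if not (auc_head.window == auc_tail.window == auc_dual.window):
        raise ValueError("AUC windows do not match")
    s = auc_head.auc + auc_tail.auc
    d = auc_dual.auc
    return {
        "sum": s,
        "dual": d,
        "difference": d - s,
        "ratio": d / s if s != 0 else np.nan,
    }
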