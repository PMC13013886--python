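"""Optimal second-sampling-angle analysis for gradient estimation.

A worm crawling through a steady concentration field can estimate the local
gradient by sampling the directional derivative along two distinct headings:
it measures the concentration at the start of a leg, at the turn point, and
at the end of the second leg, and differences successive measurements,

    d_1 = g . u(theta_1) + (eps_turn - eps_0),
    d_2 = g . u(theta_1 + delta) + (eps_2 - eps_turn),

with g the unknown 2-D gradient.  Two non-collinear samples identify g by
linear least squares; the design question is which turn angle delta between
the two sampling directions minimises the uncertainty of the *direction* of
the estimated gradient.

Two features of the sensing model matter:

* the two derivative samples share the turn-point measurement, so their
  noises are anti-correlated; the turn itself perturbs that shared sample,
  so its noise is larger than at the leg ends (``shared_noise_factor``, the
  ratio of turn-point to end-point measurement s.d., default 2 -- giving an
  effective anti-correlation of 0.8 between the two derivative noises);
* the dispersion of the direction estimate phi_hat = atan2(g_hat) is
  evaluated at finite noise (root-mean-square wrapped angular error, by
  deterministic Gauss-Hermite quadrature), not by the small-noise delta
  method.

Under independent derivative noise the optimal separation is 90 degrees;
the shared-sample anti-correlation pushes it up: the optimum exceeds
90 degrees for every initial orientation and sits near 120 degrees once the
initial orientation is averaged uniformly over the circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingDesign",
    "DesignEvaluation",
    "GradientEstimate",
    "DEFAULT_NOISE_SD",
    "DEFAULT_SHARED_NOISE_FACTOR",
    "estimate_gradient_lsq",
    "direction_uncertainty",
    "linearized_direction_uncertainty",
    "optimal_second_angle",
]

# Per-derivative-sample noise s.d. relative to a unit gradient.  The regime
# of interest is noise a sizeable fraction of the signal (the analysis
# exists because sensing is unreliable); see docs/methods.md.
DEFAULT_NOISE_SD = 0.3
# Ratio of turn-point to leg-end concentration-measurement noise s.d.
DEFAULT_SHARED_NOISE_FACTOR = 2.0


@dataclass
class SamplingDesign:
    """One two-sample design: first direction theta1 (rad, relative to the
    true gradient unless ``grad_direction`` is set), turn angle delta to the
    second direction, and the sensing-noise model."""

    theta1: float
    delta: float
    noise_sd: float = DEFAULT_NOISE_SD
    shared_noise_factor: float = DEFAULT_SHARED_NOISE_FACTOR
    grad_direction: float = 0.0
    grad_magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -np.pi < self.delta <= np.pi + 1e-12:
            raise ValueError("delta must lie in (-pi, pi]")
        if self.grad_magnitude <= 0:
            raise ValueError("grad_magnitude must be positive")
        if self.shared_noise_factor < 0:
            raise ValueError("shared_noise_factor must be nonnegative")

    @property
    def noise_correlation(self) -> float:
        """Anti-correlation -beta between the two derivative noises induced
        by the shared turn-point measurement (0 when independent)."""
        k2 = self.shared_noise_factor**2
        return -k2 / (k2 + 1.0)


@dataclass
class DesignEvaluation:
    design: SamplingDesign
    direction_uncertainty: float


@dataclass
class GradientEstimate:
    gradient: np.ndarray
    direction: float
    covariance: np.ndarray


def _wrap(a):
    return np.mod(np.asarray(a, float) + np.pi, 2 * np.pi) - np.pi


def estimate_gradient_lsq(samples, noise_sd: float = DEFAULT_NOISE_SD,
                          noise_corr: float = 0.0) -> GradientEstimate:
    """Least-squares gradient from (direction, directional derivative) pairs.

    Solves d_i = g . u(theta_i) + eps_i for g.  With iid noise the estimator
    covariance is sigma^2 (A^T A)^{-1}; a nonzero pairwise ``noise_corr``
    (two-sample designs only) propagates through A^{-1} Sigma A^{-T}.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two directional samples")
    thetas = np.array([s[0] for s in samples], float)
    d = np.array([s[1] for s in samples], float)
    A = np.column_stack([np.cos(thetas), np.sin(thetas)])
    if np.linalg.matrix_rank(A, tol=1e-10) < 2:
        raise np.linalg.LinAlgError(
            "collinear sampling directions: gradient unidentifiable"
        )
    g, *_ = np.linalg.lstsq(A, d, rcond=None)
    if noise_corr != 0.0 and len(samples) == 2:
        S = noise_sd**2 * np.array([[1.0, noise_corr], [noise_corr, 1.0]])
        Ai = np.linalg.inv(A)
        cov = Ai @ S @ Ai.T
    else:
        cov = noise_sd**2 * np.linalg.pinv(A.T @ A)
    return GradientEstimate(
        gradient=g, direction=float(np.arctan2(g[1], g[0])), covariance=cov
    )


def _gh_noise_nodes(nodes: int, corr: float):
    """2-D Gauss-Hermite nodes/weights for unit-variance noise with the
    given pairwise correlation."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(nodes)
    z = np.sqrt(2.0) * gh_x
    w = gh_w / np.sqrt(np.pi)
    Z1, Z2 = np.meshgrid(z, z, indexing="ij")
    W = np.outer(w, w).ravel()
    # Cholesky of [[1, corr], [corr, 1]]
    e1 = Z1.ravel()
    e2 = corr * Z1.ravel() + np.sqrt(1 - corr**2) * Z2.ravel()
    return e1, e2, W


def _angular_rms_error(theta1, delta, noise_over_grad, corr, nodes=40):
    """RMS wrapped angular error of the two-sample direction estimate,
    vectorised over broadcastable theta1/delta arrays.  The true gradient
    is unit magnitude along +x; noise_over_grad is the per-derivative noise
    s.d. in those units, with pairwise correlation ``corr``."""
    theta1 = np.asarray(theta1, float)
    delta = np.asarray(delta, float)
    theta2 = theta1 + delta
    e1, e2, W = _gh_noise_nodes(nodes, corr)

    c1, s1 = np.cos(theta1), np.sin(theta1)
    c2, s2 = np.cos(theta2), np.sin(theta2)
    det = c1 * s2 - s1 * c2  # sin(delta)
    shape = np.broadcast(theta1, delta).shape
    c1, s1, c2, s2, det = np.broadcast_arrays(c1, s1, c2, s2, det)

    res = np.empty(shape if shape else (1,))
    flat = res.reshape(-1)
    c1f, s1f = np.ravel(c1), np.ravel(s1)
    c2f, s2f = np.ravel(c2), np.ravel(s2)
    detf = np.ravel(det)
    sd = noise_over_grad
    for i in range(flat.size):
        dt = detf[i]
        if abs(dt) < 1e-12:
            flat[i] = np.inf
            continue
        d1 = c1f[i] + sd * e1
        d2 = c2f[i] + sd * e2
        gx = (s2f[i] * d1 - s1f[i] * d2) / dt
        gy = (-c2f[i] * d1 + c1f[i] * d2) / dt
        err = _wrap(np.arctan2(gy, gx))
        flat[i] = np.sum(W * err**2)
    res = np.sqrt(res)
    return res if shape else float(res[0])


def direction_uncertainty(design: SamplingDesign, nodes: int = 40) -> float:
    """Dispersion (RMS wrapped angular error, rad) of the estimated gradient
    direction for the given design.  delta = 0 (collinear samples) is
    reported as infinite."""
    if abs(np.sin(design.delta)) < 1e-12:
        return np.inf
    return float(
        _angular_rms_error(
            design.theta1 - design.grad_direction,
            design.delta,
            design.noise_sd / design.grad_magnitude,
            design.noise_correlation,
            nodes=nodes,
        )
    )


def linearized_direction_uncertainty(design: SamplingDesign) -> float:
    """Small-noise (delta-method) angular s.d.: the component of the
    estimator covariance orthogonal to the true gradient.  Kept as the
    analytic contrast to the finite-noise objective; with independent
    derivative noise (shared_noise_factor = 0) its orientation-averaged
    optimum is a 90-degree separation."""
    t1 = design.theta1 - design.grad_direction
    t2 = t1 + design.delta
    s = np.sin(design.delta)
    if abs(s) < 1e-12:
        return np.inf
    rho = design.noise_correlation
    c1, c2 = np.cos(t1), np.cos(t2)
    var = (design.noise_sd / design.grad_magnitude) ** 2 * (
        c1**2 + c2**2 + 2 * rho * c1 * c2
    ) / s**2
    return float(np.sqrt(var))


def optimal_second_angle(
    initial_orientation="uniform",
    noise_sd: float = DEFAULT_NOISE_SD,
    shared_noise_factor: float = DEFAULT_SHARED_NOISE_FACTOR,
    search_grid_deg: float = 0.5,
    grad_magnitude: float = 1.0,
    n_orientations: int = 72,
    nodes: int = 40,
):
    """Turn angle minimising the direction uncertainty.

    Parameters
    ----------
    initial_orientation:
        'uniform' averages the objective over a uniform initial orientation
        on the circle; a float fixes the initial orientation (rad, relative
        to the gradient); an array supplies an explicit set to average over.
    search_grid_deg:
        Resolution of the delta grid, degrees (must be <= 1).

    Returns
    -------
    (delta_star_deg, deltas_deg, uncertainty_curve): the optimum is the
    grid argmin (first minimum on ties) of the averaged RMS angular error
    and is reported as a magnitude in degrees.  The turn is taken away from
    the gradient when the initial orientation is within 90 degrees of it and
    toward the gradient otherwise; only magnitudes are scanned since the
    orientation-averaged objective is even in delta.
    """
    if search_grid_deg > 1.0:
        raise ValueError("search grid resolution must be <= 1 degree")
    deltas_deg = np.arange(search_grid_deg, 180.0 + 1e-9, search_grid_deg)
    deltas = np.deg2rad(deltas_deg)
    if isinstance(initial_orientation, str):
        if initial_orientation != "uniform":
            raise ValueError("initial_orientation must be 'uniform', a float, "
                             "or an array of angles")
        thetas = np.arange(n_orientations) * (2 * np.pi / n_orientations)
    else:
        thetas = np.atleast_1d(np.asarray(initial_orientation, float))

    sd = noise_sd / grad_magnitude
    k2 = shared_noise_factor**2
    corr = -k2 / (k2 + 1.0)
    curve = np.zeros(deltas.size)
    for th in thetas:
        errs = _angular_rms_error(np.full(deltas.size, th), deltas, sd, corr,
                                  nodes=nodes)
        curve += errs**2
    curve = np.sqrt(curve / thetas.size)
    k = int(np.argmin(curve))
    return float(deltas_deg[k]), deltas_deg, curve
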