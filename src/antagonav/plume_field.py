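"""Volatile-pheromone transport in a two-layer (air over agar) Petri-dish arena.

The assay geometry is a circular plate half-filled with agar; a pheromone
droplet sits on the lid, so the volatile phase first spreads through the air
gap and is then slowly absorbed by (and re-released from) the agar.  The
solver integrates the diffusion equation on a masked Cartesian grid with a
conservative finite-volume scheme: face conductances are harmonic means of
the cell diffusivities, walls and the circular rim are no-flux, and the
explicit time step is chosen automatically from the stability limit.  Mass
is conserved to round-off by construction.

The navigation model consumes a 2-D lateral cross-section of the field just
below the air-agar interface (``slice_field``), and the along-body
concentration-contrast statistic |C(head) - C(tail)| / C(body) quantifies how
little information a purely spatial head-tail comparison would carry
(``head_tail_contrast``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PlateGeometry",
    "TransportParams",
    "SourceSpec",
    "ConcentrationField",
    "FieldSlice2D",
    "ContrastDistribution",
    "GeometryError",
    "StabilityError",
    "solve_bilayer_diffusion",
    "slice_field",
    "head_tail_contrast",
]


class GeometryError(ValueError):
    """Raised when a source or sampling plane lies outside the arena."""


class StabilityError(RuntimeError):
    """Raised when an explicitly requested time step violates the CFL bound."""


@dataclass
class PlateGeometry:
    """Circular plate: an air gap of ``air_thickness`` above ``agar_thickness``
    of agar.  ``grid_spacing`` is the lateral cell size; ``vertical_spacing``
    the cell size along z.  The air-agar interface is at z = 0, agar below.
    All lengths in mm."""

    radius: float
    air_thickness: float = 4.0
    agar_thickness: float = 9.0
    grid_spacing: float = 1.0
    vertical_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.air_thickness <= 0 or self.agar_thickness <= 0:
            raise ValueError("layer thicknesses must be positive")
        if self.grid_spacing <= 0 or self.vertical_spacing <= 0:
            raise ValueError("grid spacings must be positive")
        if 2 * self.radius / self.grid_spacing < 10:
            raise ValueError("grid_spacing too coarse: need >= 10 lateral cells")

    @property
    def z_bottom(self) -> float:
        return -self.agar_thickness

    @property
    def z_top(self) -> float:
        return self.air_thickness


@dataclass
class TransportParams:
    """Diffusivities (mm^2/s).  The volatile diffuses ~3 orders of magnitude
    faster in air than in agar; the interface is concentration-continuous
    (no partition coefficient)."""

    D_air: float = 1.6
    D_agar: float = 1e-3
    interface_rule: str = "concentration-continuous"

    def __post_init__(self) -> None:
        if self.D_air <= 0 or self.D_agar <= 0:
            raise ValueError("diffusivities must be positive")
        if self.D_air < self.D_agar:
            raise ValueError("expected D_air >= D_agar")
        if self.interface_rule != "concentration-continuous":
            raise ValueError(f"unknown interface rule {self.interface_rule!r}")


@dataclass
class SourceSpec:
    """Droplet on the lid: initial concentration ``c0`` (mol/m^3) on a disc
    footprint in the topmost air layer, zero elsewhere."""

    center_xy: tuple[float, float] = (0.0, 0.0)
    footprint_radius: float = 1.5
    c0: float = 0.01

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError("c0 must be nonnegative")
        if self.footprint_radius <= 0:
            raise ValueError("footprint_radius must be positive")


@dataclass
class ConcentrationField:
    """Dense space-time concentration values over the bilayer arena.

    ``values`` has shape (n_times, nx, ny, nz); cells outside the circular
    rim hold 0 and are marked invalid in ``mask``.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    geometry: PlateGeometry
    transport: TransportParams
    source: SourceSpec

    def total_amount(self) -> np.ndarray:
        """Total dissolved amount per stored frame (mol/m^3 * mm^3)."""
        g = self.geometry
        cell_volume = g.grid_spacing**2 * g.vertical_spacing
        return self.values.reshape(len(self.times), -1).sum(axis=1) * cell_volume

    def layer_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean concentration over valid air cells and agar cells per frame."""
        air = self.z > 0
        agar = ~air
        m = self.mask
        vals = np.where(m[None, :, :, None], self.values, np.nan)
        air_mean = np.nanmean(vals[..., air], axis=(1, 2, 3))
        agar_mean = np.nanmean(vals[..., agar], axis=(1, 2, 3))
        return air_mean, agar_mean


def _build_grid(geometry: PlateGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = geometry
    h = g.grid_spacing
    n_lat = int(round(2 * g.radius / h))
    # cell centers symmetric about the plate center
    x = (np.arange(n_lat) - (n_lat - 1) / 2.0) * h
    y = x.copy()
    dz = g.vertical_spacing
    n_agar = max(1, int(round(g.agar_thickness / dz)))
    n_air = max(1, int(round(g.air_thickness / dz)))
    z_agar = -g.agar_thickness + (np.arange(n_agar) + 0.5) * (g.agar_thickness / n_agar)
    z_air = (np.arange(n_air) + 0.5) * (g.air_thickness / n_air)
    z = np.concatenate([z_agar, z_air])
    mask = (x[:, None] ** 2 + y[None, :] ** 2) <= g.radius**2
    return x, y, z, mask


def solve_bilayer_diffusion(
    geometry: PlateGeometry,
    transport: TransportParams,
    source: SourceSpec,
    duration: float,
    output_times: Sequence[float],
    dt: float | None = None,
    cfl_safety: float = 0.9,
) -> ConcentrationField:
    """Integrate pure diffusion of the volatile through air and agar.

    Parameters
    ----------
    duration:
        Total simulated time (s).  ``output_times`` must lie in [0, duration].
    dt:
        Optional explicit time step; raises :class:`StabilityError` if it
        violates the stability bound.  By default a stable step is chosen
        automatically.
    """
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times.size == 0:
        raise ValueError("need at least one output time")
    if output_times[0] < 0 or output_times[-1] > duration + 1e-9:
        raise ValueError("output_times must lie within [0, duration]")

    x, y, z, mask = _build_grid(geometry)
    nx, ny, nz = x.size, y.size, z.size
    h = geometry.grid_spacing

    sx, sy = source.center_xy
    if np.hypot(sx, sy) + source.footprint_radius > geometry.radius:
        raise GeometryError("source footprint extends outside the plate")

    # per-cell diffusivity by layer
    D_z = np.where(z > 0, transport.D_air, transport.D_agar)
    D = np.broadcast_to(D_z, (nx, ny, nz)).copy()
    D[~mask, :] = 0.0  # outside the rim: dead cells, zero conductance faces

    # face conductances (1/s): harmonic mean of adjacent cell diffusivities
    def _harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        s = a + b
        out = np.zeros_like(a)
        nzm = s > 0
        out[nzm] = 2 * a[nzm] * b[nzm] / s[nzm]
        out[(a == 0) | (b == 0)] = 0.0
        return out

    gx = _harm(D[:-1, :, :], D[1:, :, :]) / h**2
    gy = _harm(D[:, :-1, :], D[:, 1:, :]) / h**2
    # vertical spacing varies only through layer counts; use local dz of the
    # thinner neighbour pair (uniform dz by construction of _build_grid)
    dz_cells = np.diff(z)
    dz_face = np.broadcast_to(dz_cells, (nx, ny, nz - 1))
    gz = _harm(D[:, :, :-1], D[:, :, 1:]) / dz_face**2

    total_g = np.zeros((nx, ny, nz))
    total_g[:-1, :, :] += gx
    total_g[1:, :, :] += gx
    total_g[:, :-1, :] += gy
    total_g[:, 1:, :] += gy
    total_g[:, :, :-1] += gz
    total_g[:, :, 1:] += gz

    dt_stable = cfl_safety / float(total_g.max()) if total_g.max() > 0 else duration
    if dt is None:
        dt = dt_stable
    elif dt > dt_stable / cfl_safety:
        raise StabilityError(
            f"dt={dt:g}s exceeds the explicit stability limit {dt_stable / cfl_safety:g}s"
        )

    # initial condition: c0 on the droplet footprint in the topmost air layer
    c = np.zeros((nx, ny, nz))
    foot = ((x[:, None] - sx) ** 2 + (y[None, :] - sy) ** 2) <= source.footprint_radius**2
    c[foot & mask, nz - 1] = source.c0

    frames = np.empty((output_times.size, nx, ny, nz))
    t = 0.0
    out_i = 0
    if output_times[0] <= 1e-12:
        frames[0] = c
        out_i = 1

    while out_i < output_times.size:
        t_target = output_times[out_i]
        n_sub = max(1, int(np.ceil((t_target - t) / dt - 1e-12)))
        sub_dt = (t_target - t) / n_sub
        for _ in range(n_sub):
            lap = np.zeros_like(c)
            fx = gx * (c[1:, :, :] - c[:-1, :, :])
            lap[:-1, :, :] += fx
            lap[1:, :, :] -= fx
            fy = gy * (c[:, 1:, :] - c[:, :-1, :])
            lap[:, :-1, :] += fy
            lap[:, 1:, :] -= fy
            fz = gz * (c[:, :, 1:] - c[:, :, :-1])
            lap[:, :, :-1] += fz
            lap[:, :, 1:] -= fz
            c = c + sub_dt * lap
        t = t_target
        frames[out_i] = c
        out_i += 1

    return ConcentrationField(
        times=output_times,
        x=x,
        y=y,
        z=z,
        values=frames,
        mask=mask,
        geometry=geometry,
        transport=transport,
        source=source,
    )


@dataclass
class FieldSlice2D:
    """Lateral cross-section of a concentration field at a fixed depth.

    Exposes vectorised samplers ``sample_C(x, y, t)`` (bilinear in space,
    linear in time) and ``sample_dCdt(x, y, t)`` (forward difference between
    stored frames).  ``values`` has shape (n_times, nx, ny).
    """

    plane_z: float
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    radius: float
    source_xy: tuple[float, float] = (0.0, 0.0)

    def _lateral_weights(self, xq, yq):
        hx = self.x[1] - self.x[0]
        fx = np.clip((np.asarray(xq, float) - self.x[0]) / hx, 0, self.x.size - 1)
        fy = np.clip((np.asarray(yq, float) - self.y[0]) / hx, 0, self.y.size - 1)
        i0 = np.clip(fx.astype(int), 0, self.x.size - 2)
        j0 = np.clip(fy.astype(int), 0, self.y.size - 2)
        wx = fx - i0
        wy = fy - j0
        return i0, j0, wx, wy

    def _bilinear(self, plane: np.ndarray, i0, j0, wx, wy):
        return (
            plane[i0, j0] * (1 - wx) * (1 - wy)
            + plane[i0 + 1, j0] * wx * (1 - wy)
            + plane[i0, j0 + 1] * (1 - wx) * wy
            + plane[i0 + 1, j0 + 1] * wx * wy
        )

    def _time_bracket(self, t: float) -> tuple[int, int, float]:
        times = self.times
        if t <= times[0]:
            return 0, 0, 0.0
        if t >= times[-1]:
            return len(times) - 1, len(times) - 1, 0.0
        k = int(np.searchsorted(times, t, side="right") - 1)
        k1 = min(k + 1, len(times) - 1)
        wt = (t - times[k]) / (times[k1] - times[k]) if k1 > k else 0.0
        return k, k1, wt

    def sample_C(self, xq, yq, t: float):
        """Concentration at lateral points (xq, yq) and time t."""
        i0, j0, wx, wy = self._lateral_weights(xq, yq)
        k0, k1, wt = self._time_bracket(float(t))
        v0 = self._bilinear(self.values[k0], i0, j0, wx, wy)
        if k1 == k0:
            return v0
        v1 = self._bilinear(self.values[k1], i0, j0, wx, wy)
        return v0 * (1 - wt) + v1 * wt

    def sample_dCdt(self, xq, yq, t: float):
        """Eulerian time derivative via forward difference between frames."""
        times = self.times
        k = int(np.searchsorted(times, float(t), side="right") - 1)
        k = max(0, min(k, len(times) - 2))
        dt = times[k + 1] - times[k]
        i0, j0, wx, wy = self._lateral_weights(xq, yq)
        v0 = self._bilinear(self.values[k], i0, j0, wx, wy)
        v1 = self._bilinear(self.values[k + 1], i0, j0, wx, wy)
        return (v1 - v0) / dt


def slice_field(field: ConcentrationField, plane_z: float = -0.5) -> FieldSlice2D:
    """Extract the lateral cross-section at depth ``plane_z`` (mm, agar layer).

    Vertical interpolation is linear between the two bracketing grid planes;
    a plane exactly on a grid plane returns that plane's stored values.
    """
    g = field.geometry
    if not (g.z_bottom <= plane_z <= g.z_top):
        raise GeometryError(f"plane_z={plane_z} outside the domain")
    if plane_z > 0:
        raise GeometryError("sampling plane must lie in the agar layer (z <= 0)")
    z = field.z
    if plane_z <= z[0]:
        vals = field.values[..., 0]
    elif plane_z >= z[-1]:
        vals = field.values[..., -1]
    else:
        k = int(np.searchsorted(z, plane_z, side="right") - 1)
        w = (plane_z - z[k]) / (z[k + 1] - z[k])
        vals = field.values[..., k] * (1 - w) + field.values[..., k + 1] * w
    vals = np.ascontiguousarray(vals)
    if not field.mask.all():
        # no-flux rim: extend each frame past the circular wall with the
        # nearest interior value so bilinear sampling never mixes in the
        # zero-filled dead cells outside the plate
        from scipy.ndimage import distance_transform_edt

        _, (ii, jj) = distance_transform_edt(
            ~field.mask, return_indices=True
        )
        vals = vals[:, ii, jj]
    return FieldSlice2D(
        plane_z=plane_z,
        times=field.times,
        x=field.x,
        y=field.y,
        values=vals,
        mask=field.mask,
        radius=g.radius,
        source_xy=field.source.center_xy,
    )


@dataclass
class ContrastDistribution:
    """Empirical distribution of |C(head) - C(tail)| / C(body) samples.

    ``samples`` holds the ratios whose body (midpoint) concentration exceeds
    the guard threshold; ``flagged`` holds the numerically noisy near-zero-C
    samples, reported separately.
    """

    samples: np.ndarray
    flagged: np.ndarray
    min_body_concentration: float
    body_length: float
    n_orientations: int

    def percentile(self, q) -> np.ndarray | float:
        if self.samples.size == 0:
            raise ValueError("no unflagged samples")
        return np.percentile(self.samples, q)


def head_tail_contrast(
    slc: FieldSlice2D,
    body_length: float = 1.0,
    n_orientations: int = 16,
    min_body_concentration: float | None = None,
) -> ContrastDistribution:
    """Along-body relative concentration contrast over space, time, and
    orientation.

    For each lateral cell centre (body midpoint), stored frame, and
    orientation theta on a uniform angular grid, the head and tail sit at
    midpoint +/- (body_length/2) u(theta) and the sample is
    |C(head) - C(tail)| / C(midpoint).  Samples whose midpoint concentration
    falls below ``min_body_concentration`` (default 1e-6 times the source c0
    scale, estimated from the field maximum when no source is attached) are
    flagged instead of entering the percentile statistics.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    if min_body_concentration is None:
        min_body_concentration = 1e-6 * max(float(slc.values.max()), 1e-300)
    if min_body_concentration <= 0:
        raise ValueError("min_body_concentration must be positive (division guard)")

    half = body_length / 2.0
    xs, ys = np.meshgrid(slc.x, slc.y, indexing="ij")
    interior = slc.mask & (xs**2 + ys**2 <= (slc.radius - half) ** 2)
    px = xs[interior]
    py = ys[interior]
    thetas = np.arange(n_orientations) * (2 * np.pi / n_orientations)

    all_samples = []
    all_flags = []
    for k, t in enumerate(slc.times):
        c_mid = slc.sample_C(px, py, t)
        for th in thetas:
            ux, uy = np.cos(th), np.sin(th)
            c_head = slc.sample_C(px + half * ux, py + half * uy, t)
            c_tail = slc.sample_C(px - half * ux, py - half * uy, t)
            ok = c_mid >= min_body_concentration
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.abs(c_head - c_tail) / c_mid
            all_samples.append(ratio[ok])
            bad = ratio[~ok]
            all_flags.append(bad[np.isfinite(bad)])

    return ContrastDistribution(
        samples=np.concatenate(all_samples) if all_samples else np.empty(0),
        flagged=np.concatenate(all_flags) if all_flags else np.empty(0),
        min_body_concentration=min_body_concentration,
        body_length=body_length,
        n_orientations=n_orientations,
    )
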