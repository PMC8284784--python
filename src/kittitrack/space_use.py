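"""Colony-level kernel utilization distributions and overlap.

A utilization distribution (UD) is a probability density over space describing
where a group of birds spent its time. Positions are projected with a
spherical Lambert azimuthal equal-area projection centered on the pooled data
centroid (the study region straddles the antimeridian, and density per km²
must be area-true), a bivariate Gaussian kernel density is evaluated on a
regular km grid, and the x% isopleth — the smallest-area set of cells holding
x% of the mass — defines the "core" (50%) and "overall range" (95%) surfaces.

Overlap between two groups is Bhattacharyya's affinity,

    BA = Σ_cells sqrt(p_a · p_b) · cell_area,

computed on level-truncated UDs that are deliberately NOT renormalized, so BA
ranges from 0 (disjoint) to the truncation level itself (identical surfaces):
0.50 at the 50% level, 0.95 at the 95% level. Uncertainty comes from a
bootstrap over birds within each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import EARTH_RADIUS_KM, _check_coords

__all__ = [
    "project_points",
    "unproject_points",
    "reference_bandwidth",
    "UDGrid",
    "IsoplethUD",
    "OverlapResult",
    "kernel_ud",
    "isopleth",
    "bhattacharyya",
    "ba_bootstrap",
]


def project_points(lat, lon, center: tuple[float, float]):
    """Lambert azimuthal equal-area projection, degrees -> (x, y) in km.

    ``center`` is the (lat, lon) projection origin. The projection is exact
    and invertible everywhere except the antipode of the center, where it is
    singular (raises).
    """
    lat, lon = _check_coords(lat, lon)
    lat0, lon0 = center
    phi = np.radians(lat)
    lam = np.radians(lon)
    phi0 = np.radians(lat0)
    lam0 = np.radians(lon0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    denom = 1.0 + cosc
    if np.any(denom < 1e-12):
        raise ValueError("point at (or numerically at) the projection antipode")
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject_points(x, y, center: tuple[float, float]):
    """Inverse of :func:`project_points`; (x, y) km -> (lat, lon) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0 = np.radians(center[0])
    lam0 = np.radians(center[1])
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arcsin(
            np.clip(
                np.cos(c) * np.sin(phi0)
                + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / np.where(rho > 0, rho, 1.0), 0.0),
                -1.0,
                1.0,
            )
        )
        lam = lam0 + np.arctan2(
            x * np.sin(c),
            rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
        )
    lam = np.where(rho > 0, lam, lam0)
    lon = (np.degrees(lam) + 180.0) % 360.0 - 180.0
    return np.degrees(phi), np.where(lon == -180.0, 180.0, lon)


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Reference ("href"-style) bandwidth for an isotropic Gaussian kernel:

        h = sqrt(0.5 * (var(x) + var(y))) * n^(-1/6)

    the conventional default in kernel home-range estimation.
    """
    n = len(x)
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(
            "degenerate point set (all identical); pass an explicit bandwidth"
        )
    return float(sigma * n ** (-1.0 / 6.0))


@dataclass
class UDGrid:
    """A normalized planar density surface on a regular km grid.

    ``x`` and ``y`` hold cell-center coordinates (km, projection plane);
    ``density`` has shape (len(y), len(x)) in probability per km² and sums
    (times cell area) to 1. ``center`` is the projection origin (lat, lon).
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    cell_size_km: float
    center: tuple[float, float]
    bandwidth_km: float | None = None

    @property
    def cell_area(self) -> float:
        return self.cell_size_km**2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def same_grid(self, other: "UDGrid") -> bool:
        return (
            self.density.shape == other.density.shape
            and self.cell_size_km == other.cell_size_km
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and np.allclose(self.center, other.center)
        )


@dataclass
class IsoplethUD:
    """A UD truncated at an isopleth level: the mask marks the smallest-area
    cell set containing ``level`` of the mass; the truncated density keeps the
    parent's values inside the mask and is zero outside (not renormalized)."""

    parent: UDGrid
    level: float
    mask: np.ndarray
    truncated_density: np.ndarray = field(repr=False)

    def mass(self) -> float:
        return float(self.truncated_density.sum() * self.parent.cell_area)


@dataclass(frozen=True)
class OverlapResult:
    level: float
    ba: float
    ba_se: float
    n_boot: int


def _grid_axes(x_pts, y_pts, cell_size_km, pad_km):
    x0 = np.floor((x_pts.min() - pad_km) / cell_size_km) * cell_size_km
    x1 = np.ceil((x_pts.max() + pad_km) / cell_size_km) * cell_size_km
    y0 = np.floor((y_pts.min() - pad_km) / cell_size_km) * cell_size_km
    y1 = np.ceil((y_pts.max() + pad_km) / cell_size_km) * cell_size_km
    gx = np.arange(x0, x1 + cell_size_km / 2, cell_size_km) + cell_size_km / 2
    gy = np.arange(y0, y1 + cell_size_km / 2, cell_size_km) + cell_size_km / 2
    return gx, gy


def _kernel_sum(gx, gy, x_pts, y_pts, h) -> np.ndarray:
    """Unnormalized sum of isotropic Gaussian kernels at the grid nodes,
    shape (len(gy), len(gx)). Chunked over points to bound memory."""
    out = np.zeros((len(gy), len(gx)))
    dx2 = (gx[None, :] - np.asarray(x_pts)[:, None]) ** 2  # (n, nx)
    dy2 = (gy[None, :] - np.asarray(y_pts)[:, None]) ** 2  # (n, ny)
    # exp(-(dx²+dy²)/2h²) summed over points = einsum of separable factors
    ex = np.exp(-dx2 / (2.0 * h * h))
    ey = np.exp(-dy2 / (2.0 * h * h))
    out = np.einsum("ny,nx->yx", ey, ex)
    out /= 2.0 * np.pi * h * h
    return out


def kernel_ud(
    lat,
    lon,
    center: tuple[float, float] | None = None,
    cell_size_km: float = 50.0,
    bandwidth_km: float | None = None,
    pad_bandwidths: float = 3.0,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> UDGrid:
    """Bivariate Gaussian kernel UD of a point set on an equal-area km grid.

    The grid covers the data's bounding box padded by ``pad_bandwidths``
    bandwidths (or a caller-supplied ``grid`` of (x, y) cell centers, e.g. a
    shared grid for two groups). Density is renormalized so the discrete mass
    is exactly 1. Requires at least 5 points.
    """
    lat, lon = _check_coords(lat, lon)
    lat = np.atleast_1d(lat)
    lon = np.atleast_1d(lon)
    if lat.size < 5:
        raise ValueError("kernel UD needs at least 5 points")
    if center is None:
        from .trajectories import geographic_midpoint

        center = geographic_midpoint(lat, lon)
    x, y = project_points(lat, lon, center)
    h = reference_bandwidth(x, y) if bandwidth_km is None else float(bandwidth_km)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        gx, gy = _grid_axes(x, y, cell_size_km, pad_bandwidths * h)
    else:
        gx, gy = grid
    dens = _kernel_sum(gx, gy, x, y, h)
    mass = dens.sum() * cell_size_km**2
    if mass <= 0:
        raise ValueError("zero mass on grid; grid does not cover the data")
    dens /= mass
    return UDGrid(x=gx, y=gy, density=dens, cell_size_km=cell_size_km, center=center, bandwidth_km=h)


def isopleth(ud: UDGrid, level: float) -> IsoplethUD:
    """Truncate a UD at an isopleth level.

    Cells are ranked by density; the mask is the minimal prefix whose
    cumulative mass reaches ``level``, i.e. all cells at or above a density
    threshold. The truncated density is not renormalized, so its mass lies in
    [level, level + max single-cell mass).
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) * ud.cell_area
    # number of cells needed to reach the level (all positive cells at level 1)
    if level == 1.0:
        k = int(np.sum(flat > 0))
    else:
        k = int(np.searchsorted(cum, level) + 1)
        k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask &= flat > 0
    mask = mask.reshape(ud.density.shape)
    trunc = np.where(mask, ud.density, 0.0)
    return IsoplethUD(parent=ud, level=level, mask=mask, truncated_density=trunc)


def bhattacharyya(a: IsoplethUD, b: IsoplethUD) -> float:
    """Bhattacharyya's affinity Σ sqrt(p_a·p_b)·cell_area of two truncated UDs.

    Both must live on the same grid and level; no implicit resampling is done.
    Bounded by the truncation level (up to isopleth quantization), attained
    only when the truncated surfaces coincide.
    """
    if a.level != b.level:
        raise ValueError("isopleth levels differ")
    if not a.parent.same_grid(b.parent):
        raise ValueError("UD grids differ; rebuild both on a shared grid")
    return float(
        np.sum(np.sqrt(a.truncated_density * b.truncated_density)) * a.parent.cell_area
    )


def _pooled_center_and_grid(dfs, cell_size_km, bandwidth_km, pad_bandwidths):
    from .trajectories import geographic_midpoint

    lat = np.concatenate([d["lat"].to_numpy() for d in dfs])
    lon = np.concatenate([d["lon"].to_numpy() for d in dfs])
    center = geographic_midpoint(lat, lon)
    x, y = project_points(lat, lon, center)
    h = reference_bandwidth(x, y) if bandwidth_km is None else float(bandwidth_km)
    gx, gy = _grid_axes(x, y, cell_size_km, pad_bandwidths * h)
    return center, (gx, gy), h


def colony_ud_pair(
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    cell_size_km: float = 50.0,
    bandwidth_km: float | None = None,
) -> tuple[UDGrid, UDGrid]:
    """Two pooled colony UDs on one shared grid (shared projection center,
    extent and bandwidth), ready for overlap computation."""
    center, grid, h = _pooled_center_and_grid(
        [positions_a, positions_b], cell_size_km, bandwidth_km, 3.0
    )
    ud_a = kernel_ud(
        positions_a["lat"], positions_a["lon"], center=center,
        cell_size_km=cell_size_km, bandwidth_km=h, grid=grid,
    )
    ud_b = kernel_ud(
        positions_b["lat"], positions_b["lon"], center=center,
        cell_size_km=cell_size_km, bandwidth_km=h, grid=grid,
    )
    return ud_a, ud_b


def ba_overlap(
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    level: float,
    cell_size_km: float = 50.0,
    bandwidth_km: float | None = None,
) -> float:
    """Point-estimate BA between two groups' level-truncated pooled UDs."""
    ud_a, ud_b = colony_ud_pair(positions_a, positions_b, cell_size_km, bandwidth_km)
    return bhattacharyya(isopleth(ud_a, level), isopleth(ud_b, level))


def ba_bootstrap(
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    level: float,
    n_boot: int = 100,
    seed: int | None = None,
    cell_size_km: float = 50.0,
    bandwidth_km: float | None = None,
) -> OverlapResult:
    """BA with a bootstrap-over-birds standard error.

    Birds are resampled with replacement within each group; the pooled UD and
    BA are recomputed for each resample on the full-data grid and bandwidth
    (kept fixed so resamples measure sampling variability of the surfaces, not
    of the smoothing parameter). The point estimate uses the full data;
    ``ba_se`` is the SD of the bootstrap distribution.
    """
    birds_a = sorted(positions_a["bird_id"].unique())
    birds_b = sorted(positions_b["bird_id"].unique())
    if len(birds_a) < 2 or len(birds_b) < 2:
        raise ValueError("bootstrap needs at least 2 birds per group")
    center, (gx, gy), h = _pooled_center_and_grid(
        [positions_a, positions_b], cell_size_km, bandwidth_km, 3.0
    )
    area = cell_size_km**2

    def bird_grids(df, birds):
        grids = {}
        for bird in birds:
            sub = df[df["bird_id"] == bird]
            x, y = project_points(sub["lat"].to_numpy(), sub["lon"].to_numpy(), center)
            grids[bird] = _kernel_sum(gx, gy, x, y, h)  # unnormalized kernel sum
        return grids

    grids_a = bird_grids(positions_a, birds_a)
    grids_b = bird_grids(positions_b, birds_b)

    def pooled_ud(grids, sample):
        dens = np.zeros((len(gy), len(gx)))
        for bird in sample:
            dens += grids[bird]
        dens /= dens.sum() * area
        return UDGrid(x=gx, y=gy, density=dens, cell_size_km=cell_size_km,
                      center=center, bandwidth_km=h)

    def ba_of(sample_a, sample_b):
        ia = isopleth(pooled_ud(grids_a, sample_a), level)
        ib = isopleth(pooled_ud(grids_b, sample_b), level)
        return bhattacharyya(ia, ib)

    ba_point = ba_of(birds_a, birds_b)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for r in range(n_boot):
        sa = [birds_a[i] for i in rng.integers(0, len(birds_a), len(birds_a))]
        sb = [birds_b[i] for i in rng.integers(0, len(birds_b), len(birds_b))]
        boots[r] = ba_of(sa, sb)
    return OverlapResult(level=level, ba=ba_point, ba_se=float(np.std(boots, ddof=1)), n_boot=n_boot)
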