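"""Divergence of the tissue velocity field on an interpolated surface.

The monolayer is treated as a laminar 2D surface embedded in 3D.  Per frame
pair, cell positions define a height field z(x, y) interpolated piecewise
linearly over their Delaunay triangulation onto a regular grid whose spacing
respects the sampling bound dx_grid < 2 x nucleus size; each velocity
component is interpolated across the grid with a spline method.  2D
divergences are taken in the xy, yz and xz planes by finite differences
along grid lines and combined algebraically — half their sum — which equals
the full dvx/dx + dvy/dy + dvz/dz since each partial appears in exactly two
planes.  Negative values mean local constriction, positive expansion; the
arithmetic mean over the valid surface nodes summarizes each frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RBFInterpolator, SmoothBivariateSpline
from scipy.spatial import Delaunay, QhullError

from tissuekin.midline import Midline
from tissuekin.tracks import TrackSet, estimate_velocities

logger = logging.getLogger(__name__)

DEFAULT_SLOPE_EPS = 1e-3


@dataclass
class SurfaceGrid:
    """Regular xy lattice with interpolated surface height.

    Arrays are indexed [iy, ix].  ``valid`` marks nodes inside the convex
    hull of the data points; ``z`` is NaN outside.
    """

    xs: np.ndarray
    ys: np.ndarray
    spacing: float
    valid: np.ndarray
    z: np.ndarray
    tri: Delaunay

    @property
    def shape(self):
        return (len(self.ys), len(self.xs))

    def meshgrid(self):
        return np.meshgrid(self.xs, self.ys)


@dataclass
class VelocityField:
    """Velocity components (µm/s) on a SurfaceGrid, NaN at invalid nodes."""

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray


def build_grid(points, nucleus_size: float, spacing: Optional[float] = None) -> SurfaceGrid:
    """Build the interpolation lattice over the xy bounding box of the data.

    Spacing defaults to ``nucleus_size`` and is capped just below
    2 x nucleus_size (the sampling bound for nucleus-sized features).
    Node validity is membership in the Delaunay triangulation of the (x, y)
    data; fewer than 3 non-collinear points is an error.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if nucleus_size <= 0:
        raise ValueError("nucleus_size must be positive")
    cap = 2.0 * nucleus_size * (1.0 - 1e-9)
    dx = min(spacing if spacing is not None else nucleus_size, cap)
    xy = P[:, :2]
    if len(xy) < 3:
        raise ValueError("need at least 3 points to build a surface grid")
    try:
        tri = Delaunay(xy)
    except QhullError as e:
        raise ValueError("degenerate (collinear?) point cloud: cannot triangulate") from e
    if tri.simplices.size == 0:
        raise ValueError("degenerate point cloud: empty triangulation")
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    xs = np.arange(xmin, xmax + dx / 2, dx)
    ys = np.arange(ymin, ymax + dx / 2, dx)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    valid = (tri.find_simplex(nodes) >= 0).reshape(X.shape)
    z = np.full(X.shape, np.nan)
    return SurfaceGrid(xs=xs, ys=ys, spacing=dx, valid=valid, z=z, tri=tri)


def interpolate_height(points, grid: SurfaceGrid) -> SurfaceGrid:
    """Fill grid.z by piecewise-linear (Delaunay) interpolation of the
    sample z values; nodes outside the hull stay invalid (no
    extrapolation)."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] < 3:
        raise ValueError("points must carry z for height interpolation")
    interp = LinearNDInterpolator(grid.tri, P[:, 2])
    X, Y = grid.meshgrid()
    z = interp(X, Y)
    z[~grid.valid] = np.nan
    grid.z = z
    grid.valid = grid.valid & np.isfinite(z)
    return grid


def interpolate_velocity(
    samples: pd.DataFrame,
    grid: SurfaceGrid,
    method: str = "tps",
    smoothing: float = 0.0,
    degree: int = 3,
) -> VelocityField:
    """Interpolate each velocity component over (x, y) onto the grid.

    method='tps' (default): thin-plate smoothing spline (exact interpolant
    at smoothing 0, reproduces linear fields).  method='fitpack': FITPACK
    bivariate smoothing spline of the given degree.  ``smoothing`` >= 0 is
    the respective backend's smoothing parameter.
    """
    xy = samples[["x_um", "y_um"]].to_numpy(float)
    if method == "tps" and len(xy) < 3:
        raise ValueError("need at least 3 velocity samples")
    if method == "fitpack" and len(xy) < (degree + 1) ** 2:
        raise ValueError(
            f"{len(xy)} samples insufficient for degree-{degree} spline; lower the degree"
        )
    X, Y = grid.meshgrid()
    pts = np.column_stack([X[grid.valid], Y[grid.valid]])
    comps = {}
    for name in ("vx_um_s", "vy_um_s", "vz_um_s"):
        vals = samples[name].to_numpy(float)
        if method == "tps":
            f = RBFInterpolator(xy, vals, kernel="thin_plate_spline",
                                smoothing=smoothing, degree=1)
            est = f(pts)
        elif method == "fitpack":
            spl = SmoothBivariateSpline(xy[:, 0], xy[:, 1], vals,
                                        kx=degree, ky=degree, s=smoothing)
            est = spl(pts[:, 0], pts[:, 1], grid=False)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
        arr = np.full(grid.shape, np.nan)
        arr[grid.valid] = est
        comps[name] = arr
    return VelocityField(vx=comps["vx_um_s"], vy=comps["vy_um_s"], vz=comps["vz_um_s"])


def _masked_derivative(F: np.ndarray, valid: np.ndarray, spacing: float, axis: int) -> np.ndarray:
    """d/dx along grid lines: central differences where both neighbors are
    valid, one-sided at the hull boundary, NaN where no valid neighbor."""
    Fm = np.where(valid, F, np.nan)
    plus = np.full_like(Fm, np.nan)
    minus = np.full_like(Fm, np.nan)
    if axis == 1:
        plus[:, :-1] = Fm[:, 1:]
        minus[:, 1:] = Fm[:, :-1]
    else:
        plus[:-1, :] = Fm[1:, :]
        minus[1:, :] = Fm[:-1, :]
    has_p = np.isfinite(plus)
    has_m = np.isfinite(minus)
    out = np.full_like(Fm, np.nan)
    both = has_p & has_m & valid
    out[both] = (plus[both] - minus[both]) / (2 * spacing)
    fwd = has_p & ~has_m & valid
    out[fwd] = (plus[fwd] - Fm[fwd]) / spacing
    bwd = ~has_p & has_m & valid
    out[bwd] = (Fm[bwd] - minus[bwd]) / spacing
    return out


def _guarded_dvz_dz(field: VelocityField, grid: SurfaceGrid, axis: int,
                    slope_eps: float) -> np.ndarray:
    """dvz/dz along one grid-line family, as (dvz/ds)/(dz/ds) with the
    contribution set to zero where the height slope is below slope_eps
    (surface locally flat along that line: the term must vanish)."""
    dvz = _masked_derivative(field.vz, grid.valid, grid.spacing, axis)
    dz = _masked_derivative(grid.z, grid.valid, grid.spacing, axis)
    out = np.zeros(grid.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dvz / dz
    use = np.isfinite(dz) & (np.abs(dz) > slope_eps) & np.isfinite(ratio)
    out[use] = ratio[use]
    out[~(np.isfinite(dvz) & np.isfinite(dz))] = np.nan
    return out


def planar_divergence(
    field: VelocityField,
    grid: SurfaceGrid,
    plane: str,
    slope_eps: float = DEFAULT_SLOPE_EPS,
) -> np.ndarray:
    """2D divergence in one coordinate plane, per node (1/s; NaN where a
    required derivative has no valid neighbor).

    xy: dvx/dx + dvy/dy.  xz: dvx/dx + dvz/dz with the z-derivative taken
    along x grid lines.  yz: dvy/dy + dvz/dz along y grid lines.  The
    dvz/dz term is guarded to zero where the surface is locally flat along
    the line (|dz/ds| <= slope_eps).
    """
    if plane == "xy":
        return (_masked_derivative(field.vx, grid.valid, grid.spacing, axis=1)
                + _masked_derivative(field.vy, grid.valid, grid.spacing, axis=0))
    if plane == "xz":
        return (_masked_derivative(field.vx, grid.valid, grid.spacing, axis=1)
                + _guarded_dvz_dz(field, grid, axis=1, slope_eps=slope_eps))
    if plane == "yz":
        return (_masked_derivative(field.vy, grid.valid, grid.spacing, axis=0)
                + _guarded_dvz_dz(field, grid, axis=0, slope_eps=slope_eps))
    raise ValueError(f"unknown plane {plane!r} (expected xy, yz or xz)")


def combine_divergence(d_xy: np.ndarray, d_yz: np.ndarray, d_xz: np.ndarray) -> np.ndarray:
    """Half the sum of the three planar divergences = full 3D divergence
    dvx/dx + dvy/dy + dvz/dz (each partial appears in exactly two planes)."""
    if not (d_xy.shape == d_yz.shape == d_xz.shape):
        raise ValueError("planar divergence fields on mismatched grids")
    return (d_xy + d_yz + d_xz) / 2.0


def intrinsic_divergence(field: VelocityField, grid: SurfaceGrid) -> np.ndarray:
    """First-fundamental-form surface divergence (sensitivity-analysis
    mode): div_S v = tr(g^-1 J^T Dv) with J the embedding Jacobian of
    z = f(x, y) and Dv the grid gradient of the velocity components."""
    zx = _masked_derivative(grid.z, grid.valid, grid.spacing, axis=1)
    zy = _masked_derivative(grid.z, grid.valid, grid.spacing, axis=0)
    d = {}
    for name, comp in (("vx", field.vx), ("vy", field.vy), ("vz", field.vz)):
        d[name + "_x"] = _masked_derivative(comp, grid.valid, grid.spacing, axis=1)
        d[name + "_y"] = _masked_derivative(comp, grid.valid, grid.spacing, axis=0)
    # J^T Dv entries
    a11 = d["vx_x"] + zx * d["vz_x"]
    a12 = d["vx_y"] + zx * d["vz_y"]
    a21 = d["vy_x"] + zy * d["vz_x"]
    a22 = d["vy_y"] + zy * d["vz_y"]
    g11 = 1 + zx**2
    g12 = zx * zy
    g22 = 1 + zy**2
    det = g11 * g22 - g12**2
    return (g22 * a11 - g12 * a21 - g12 * a12 + g11 * a22) / det


def mean_divergence(div: np.ndarray) -> float:
    """Unweighted arithmetic mean of nodal divergence over valid nodes;
    NaN if no node is valid."""
    if np.all(~np.isfinite(div)):
        return float("nan")
    return float(np.nanmean(div))


@dataclass(frozen=True)
class DivergenceParams:
    """Parameters of the divergence stage.

    nucleus_size (µm) sets the default grid spacing (ceiling 2x);
    ``smoothing`` is the velocity-spline smoothing parameter (0 =
    interpolating, raise for noisy data); ``slope_eps`` guards the
    out-of-plane derivative on locally flat surface lines; mode 'planar'
    is the plane-combination divergence, 'intrinsic' the
    first-fundamental-form variant.
    """

    nucleus_size: float = 5.0
    spacing: Optional[float] = None
    method: str = "tps"
    smoothing: float = 0.0
    degree: int = 3
    slope_eps: float = DEFAULT_SLOPE_EPS
    mode: str = "planar"
    min_samples: int = 4
    #: 'auto': estimate z tracking noise from per-track second differences
    #: and raise the slope guard above the noise floor; a float fixes the
    #: noise sd (µm); None disables the noise-aware guard.
    z_noise_sd: object = "auto"
    noise_guard_factor: float = 4.0


@dataclass
class DivergenceResult:
    """Nodal divergence tables and per-frame means for a track set.

    ``nodes``: frame, x_um, y_um, z_um, div_per_s.
    ``frame_means``: per frame-pair mean (s^-1 and per-frame units),
    node count, minimum node and (optionally) its distance to the midline.
    ``grand_mean``/``grand_sd``: mean ± s.d. of the per-frame means.
    """

    nodes: pd.DataFrame
    frame_means: pd.DataFrame
    grand_mean: float
    grand_sd: float
    skipped_frames: list

    def to_csv(self, nodes_path=None, means_path=None) -> None:
        if nodes_path is not None:
            self.nodes.to_csv(nodes_path, index=False)
        if means_path is not None:
            self.frame_means.to_csv(means_path, index=False)


def estimate_z_noise(ts: TrackSet) -> float:
    """Tracking-noise s.d. of the z coordinate (µm), from per-track second
    differences: for smooth motion sampled with i.i.d. noise of variance s²,
    the second difference has variance 6 s²."""
    d2 = []
    for _, g in ts.df.groupby("track_id", sort=False):
        z = g.sort_values("frame")["z_um"].to_numpy(float)
        if len(z) >= 3:
            d2.append(np.diff(z, n=2))
    if not d2:
        return 0.0
    return float(np.sqrt(np.mean(np.concatenate(d2) ** 2) / 6.0))


def _effective_slope_eps(params: DivergenceParams, spacing: float,
                         z_noise: float) -> float:
    """Slope guard threshold: the configured minimum, raised above the
    noise floor of a central-difference slope of a piecewise-linear height
    field built from z samples with the given noise sd."""
    if params.z_noise_sd is None:
        return params.slope_eps
    floor = params.noise_guard_factor * np.sqrt(2.0) * z_noise / (2.0 * spacing)
    return max(params.slope_eps, floor)


def divergence_series(
    ts: TrackSet,
    params: DivergenceParams = DivergenceParams(),
    midline: Optional[Midline] = None,
) -> DivergenceResult:
    """Run the full divergence pipeline over every consecutive frame pair.

    Per pair: velocity samples (forward differences anchored at the earlier
    frame), grid build from those sample positions, height and velocity
    interpolation, planar divergences, combination and surface mean.  The
    per-frame table records where the most negative node lies; with a
    midline given, also its distance to it — constriction hotspots at the
    midline are the expected signature of a converging monolayer.
    """
    vel = estimate_velocities(ts, scheme="forward")
    frames = np.sort(vel["frame"].unique())
    if params.z_noise_sd == "auto":
        z_noise = estimate_z_noise(ts)
    elif params.z_noise_sd is None:
        z_noise = 0.0
    else:
        z_noise = float(params.z_noise_sd)
    node_tables, mean_rows, skipped = [], [], []
    for f in frames:
        sub = vel[vel["frame"] == f]
        if len(sub) < max(3, params.min_samples):
            skipped.append(int(f))
            continue
        pts = sub[["x_um", "y_um", "z_um"]].to_numpy(float)
        try:
            grid = build_grid(pts, params.nucleus_size, params.spacing)
            grid = interpolate_height(pts, grid)
            field = interpolate_velocity(sub, grid, method=params.method,
                                         smoothing=params.smoothing,
                                         degree=params.degree)
        except ValueError as e:
            logger.warning("frame %s skipped: %s", f, e)
            skipped.append(int(f))
            continue
        if params.mode == "intrinsic":
            div = intrinsic_divergence(field, grid)
        else:
            eps = _effective_slope_eps(params, grid.spacing, z_noise)
            d_xy = planar_divergence(field, grid, "xy", eps)
            d_yz = planar_divergence(field, grid, "yz", eps)
            d_xz = planar_divergence(field, grid, "xz", eps)
            div = combine_divergence(d_xy, d_yz, d_xz)
        ok = np.isfinite(div)
        if not ok.any():
            skipped.append(int(f))
            continue
        X, Y = grid.meshgrid()
        node_tables.append(pd.DataFrame({
            "frame": int(f), "x_um": X[ok], "y_um": Y[ok], "z_um": grid.z[ok],
            "div_per_s": div[ok],
        }))
        imin = np.nanargmin(np.where(ok, div, np.nan))
        iy, ix = np.unravel_index(imin, div.shape)
        t_s = float(sub["t_s"].iloc[0])
        row = {
            "frame": int(f), "t_s": t_s,
            "mean_div_per_s": mean_divergence(div),
            "mean_div_per_frame": mean_divergence(div) * ts.frame_interval,
            "n_nodes": int(ok.sum()),
            "min_div_per_s": float(div[iy, ix]),
            "min_x_um": float(X[iy, ix]), "min_y_um": float(Y[iy, ix]),
            "min_z_um": float(grid.z[iy, ix]),
            "grid_spacing_um": grid.spacing,
        }
        if midline is not None:
            p = np.array([row["min_x_um"], row["min_y_um"], row["min_z_um"]])
            row["min_dist_to_midline_um"] = float(midline.distance_to(p.reshape(1, 3), mode="xy")[0])
        mean_rows.append(row)
    nodes = (pd.concat(node_tables, ignore_index=True) if node_tables
             else pd.DataFrame(columns=["frame", "x_um", "y_um", "z_um", "div_per_s"]))
    frame_means = pd.DataFrame(mean_rows)
    if len(frame_means):
        gm = float(frame_means["mean_div_per_s"].mean())
        gs = float(frame_means["mean_div_per_s"].std(ddof=1)) if len(frame_means) > 1 else 0.0
    else:
        gm, gs = float("nan"), float("nan")
    return DivergenceResult(nodes=nodes, frame_means=frame_means,
                            grand_mean=gm, grand_sd=gs, skipped_frames=skipped)
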