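"""Synthetic scenes with analytically known kinematics.

Everything downstream — velocity estimation, the surface divergence field,
midline directionality, morphometrics — is validated against scenes whose
ground truth is known in closed form: cells advected by a prescribed flow on
a height-field surface, divisions with known plane orientations, and
polygonal cell shapes with prescribed areas.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from tissuekin.midline import Midline
from tissuekin.morphometrics import (
    DivisionEvent,
    ShapeSeries,
    classify_division_angle,
)
from tissuekin.specs import (
    DivisionSpec,
    FlowSpec,
    SceneSpec,
    ShapeSpec,
    SurfaceSpec,
    flow_velocity,
)
from tissuekin.tracks import TrackSet

#: default height-slope magnitude below which the out-of-plane divergence
#: term is treated as zero (surface locally flat along that grid line)
DEFAULT_SLOPE_EPS = 1e-3


# --------------------------------------------------------------------------
# track generation

def generate_tracks(scene: SceneSpec) -> TrackSet:
    """Advect cells through the scene's flow on its surface.

    Cells are seeded uniformly over the surface extent and stepped with
    explicit Euler (``scene.substeps`` sub-steps per frame interval), each
    sub-step followed by projection back onto the surface z = f(x, y).
    I.i.d. Gaussian noise of sd ``scene.noise_sd`` is then added per
    coordinate per frame.  The output carries noise-free ground-truth
    positions (``gt_x_um`` ...) alongside the noisy ones, and a
    ``truncated`` flag for tracks cut at the surface boundary.
    """
    rng = np.random.default_rng(scene.seed)
    surf, flow = scene.surface, scene.flow
    n, m = scene.n_cells, scene.n_frames
    dt_sub = scene.frame_interval / scene.substeps

    P = np.empty((n, m, 3))
    P[:, 0, 0] = rng.uniform(-surf.extent, surf.extent, size=n)
    P[:, 0, 1] = rng.uniform(-surf.extent, surf.extent, size=n)
    P[:, 0, 2] = surf.height(P[:, 0, 0], P[:, 0, 1])
    last_ok = np.full(n, m - 1, dtype=int)

    cur = P[:, 0, :].copy()
    for f in range(1, m):
        for _ in range(scene.substeps):
            v = flow_velocity(flow, cur)
            cur[:, :2] += v[:, :2] * dt_sub
            cur[:, 2] = surf.height(cur[:, 0], cur[:, 1])
        out = ~surf.in_bounds(cur[:, 0], cur[:, 1])
        newly_out = out & (last_ok == m - 1)
        last_ok[newly_out] = f - 1
        P[:, f, :] = cur

    noise = rng.standard_normal((n, m, 3)) * scene.noise_sd
    t = np.arange(m) * scene.frame_interval

    rows = []
    for i in range(n):
        upto = last_ok[i] + 1
        rows.append(pd.DataFrame({
            "track_id": i,
            "frame": np.arange(upto),
            "t_s": t[:upto],
            "x_um": P[i, :upto, 0] + noise[i, :upto, 0],
            "y_um": P[i, :upto, 1] + noise[i, :upto, 1],
            "z_um": P[i, :upto, 2] + noise[i, :upto, 2],
            "gt_x_um": P[i, :upto, 0],
            "gt_y_um": P[i, :upto, 1],
            "gt_z_um": P[i, :upto, 2],
            "truncated": last_ok[i] < m - 1,
        }))
    df = pd.concat(rows, ignore_index=True)
    # drop tracks truncated before their second frame (no kinematics in them)
    counts = df.groupby("track_id")["frame"].transform("size")
    df = df[counts >= 2].reset_index(drop=True)
    return TrackSet.from_dataframe(df)


# --------------------------------------------------------------------------
# divergence oracle

def _closed_form_flat_divergence(flow: FlowSpec, P: np.ndarray) -> np.ndarray:
    """Exact divergence of the flow's xy components on a flat surface
    (the out-of-plane terms vanish under the slope guard)."""
    n = P.shape[0]
    if flow.kind in ("translation", "rotation"):
        return np.zeros(n)
    if flow.kind == "isotropic_contraction":
        return np.full(n, -2.0 * flow.rate)
    if flow.kind == "isotropic_expansion":
        return np.full(n, 2.0 * flow.rate)
    if flow.kind == "midline_convergence":
        return np.full(n, -flow.rate)
    if flow.kind == "midline_sink":
        from tissuekin.specs import _line_offset_xy
        off = _line_offset_xy(P, flow.center, flow.axis)
        s2 = np.sum(off[:, :2] ** 2, axis=1) / flow.width**2
        # d/ds[-a s (1-s^2)^2] = -a (1-s^2)(1-5 s^2) inside the support
        return np.where(s2 < 1.0,
                        -flow.rate * (1.0 - s2) * (1.0 - 5.0 * s2), 0.0)
    if flow.kind == "composite":
        return np.sum([_closed_form_flat_divergence(p, P) for p in flow.parts], axis=0)
    raise ValueError(flow.kind)


def analytic_divergence(
    flow: FlowSpec,
    surface: SurfaceSpec,
    points,
    slope_eps: float = DEFAULT_SLOPE_EPS,
    h: float = 0.05,
) -> np.ndarray:
    """Ground-truth divergence of the surface-constrained flow at points on
    the surface, matching the pipeline's measurement convention.

    The measured quantity is D = dvx/dx + dvy/dy + (Tx + Ty)/2 where
    Tx = (dvz/dx)/(dz/dx) (and likewise Ty) is the out-of-plane term taken
    along a surface line, guarded to zero where the height slope magnitude
    is below ``slope_eps``; vz is the vertical velocity a surface-bound
    particle acquires, vz = fx*vx + fy*vy.  On flat surfaces the closed
    form is returned; on curved ones central finite differences at spacing
    ``h`` µm are used.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    scalar_in = np.asarray(points).ndim == 1
    if P.shape[1] == 2:
        P = np.column_stack([P, surface.height(P[:, 0], P[:, 1])])
    if not np.all(surface.in_bounds(P[:, 0], P[:, 1])):
        raise ValueError("point(s) outside the surface extent")

    if surface.kind == "flat":
        out = _closed_form_flat_divergence(flow, P)
        return float(out[0]) if scalar_in else out

    x, y = P[:, 0], P[:, 1]

    def vfield(xx, yy):
        zz = surface.height(xx, yy)
        v = flow_velocity(flow, np.column_stack([xx, yy, zz]))
        fx = (surface.height(xx + h, yy) - surface.height(xx - h, yy)) / (2 * h)
        fy = (surface.height(xx, yy + h) - surface.height(xx, yy - h)) / (2 * h)
        vz = fx * v[:, 0] + fy * v[:, 1]
        return v[:, 0], v[:, 1], vz, zz

    vx_xp, _, vz_xp, z_xp = vfield(x + h, y)
    vx_xm, _, vz_xm, z_xm = vfield(x - h, y)
    _, vy_yp, vz_yp, z_yp = vfield(x, y + h)
    _, vy_ym, vz_ym, z_ym = vfield(x, y - h)

    dvx_dx = (vx_xp - vx_xm) / (2 * h)
    dvy_dy = (vy_yp - vy_ym) / (2 * h)
    slope_x = (z_xp - z_xm) / (2 * h)
    slope_y = (z_yp - z_ym) / (2 * h)
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = np.where(np.abs(slope_x) > slope_eps,
                      (vz_xp - vz_xm) / (z_xp - z_xm), 0.0)
        ty = np.where(np.abs(slope_y) > slope_eps,
                      (vz_yp - vz_ym) / (z_yp - z_ym), 0.0)
    out = dvx_dx + dvy_dy + 0.5 * (tx + ty)
    return float(out[0]) if scalar_in else out


# --------------------------------------------------------------------------
# division events

Dist = Union[float, Tuple, Callable]


def _sample(dist: Dist, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(dist):
        return np.asarray(dist(rng, n), dtype=float)
    if isinstance(dist, (int, float)):
        return np.full(n, float(dist))
    name = dist[0]
    if name == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if name == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    raise ValueError(f"unknown distribution spec {dist!r}")


def generate_divisions(
    n: int,
    midline: Midline,
    distance_dist: Dist = ("uniform", 0.0, 150.0),
    angle_dist: Dist = ("uniform", 0.0, 90.0),
    seed: int = 0,
    t_range: Tuple[float, float] = (0.0, 0.0),
) -> List[DivisionEvent]:
    """Sample division events with exactly known plane angle (degrees in
    [0, 90] to the midline) and perpendicular distance (µm >= 0) to the
    midline; the recorded class is the ground-truth label."""
    rng = np.random.default_rng(seed)
    angles = _sample(angle_dist, rng, n)
    dists = _sample(distance_dist, rng, n)
    if np.any((angles < 0) | (angles > 90)):
        raise ValueError("angle distribution must be supported on [0, 90] degrees")
    if np.any(dists < 0):
        raise ValueError("distance distribution must be non-negative")

    u = midline.direction("3d")
    m = np.array([-u[1], u[0], 0.0])
    if np.linalg.norm(m) < 1e-12:  # midline along z: any horizontal normal works
        m = np.array([1.0, 0.0, 0.0])
    nhat = m - (m @ u) * u
    nhat = nhat / np.linalg.norm(nhat)

    s = rng.uniform(0.0, 1.0, size=n)
    tvals = rng.uniform(t_range[0], t_range[1], size=n) if t_range[1] > t_range[0] \
        else np.full(n, float(t_range[0]))
    events = []
    for i in range(n):
        base = midline.a + s[i] * (midline.b - midline.a)
        pos = base + dists[i] * nhat
        a_rad = np.radians(angles[i])
        plane_dir = np.cos(a_rad) * u + np.sin(a_rad) * nhat
        events.append(DivisionEvent(
            t_s=float(tvals[i]), position=pos, plane_dir=plane_dir,
            angle_deg=float(angles[i]), distance_um=float(dists[i]),
            cls=classify_division_angle(float(angles[i])),
        ))
    return events


# --------------------------------------------------------------------------
# cell shapes

def generate_cell_shapes(
    shape_spec: ShapeSpec,
    reference,
    n_frames: int,
    seed: int = 0,
) -> ShapeSeries:
    """Polygonal cell outlines over time with known areas.

    Cells are regular ``n_vertices``-gons (random orientation) placed
    uniformly over the extent; initial area interpolates from ``area_near``
    at the reference to ``area_far`` at ``distance_scale``.  Cells whose
    initial centroid distance to the reference is below ``shrink_radius``
    shrink about their centroid by ``shrink_factor`` per frame.  The
    returned series carries a ``truth`` table (cell_id, frame,
    true_area_um2, init_dist_um).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    sp = shape_spec
    ref = np.asarray(reference, dtype=float).reshape(-1)[:2]

    centers = rng.uniform(-sp.extent, sp.extent, size=(sp.n_cells, 2))
    phases = rng.uniform(0, 2 * np.pi, size=sp.n_cells)
    d0 = np.hypot(centers[:, 0] - ref[0], centers[:, 1] - ref[1])
    frac = np.minimum(d0 / sp.distance_scale, 1.0)
    area0 = sp.area_near + (sp.area_far - sp.area_near) * frac

    k = sp.n_vertices
    # circumradius of a regular k-gon of area A
    r0 = np.sqrt(2.0 * area0 / (k * np.sin(2 * np.pi / k)))
    ang = 2 * np.pi * np.arange(k) / k

    rows, truth = [], []
    for i in range(sp.n_cells):
        shrinks = d0[i] < sp.shrink_radius
        for f in range(n_frames):
            scale = sp.shrink_factor**f if shrinks else 1.0
            vx = centers[i, 0] + r0[i] * scale * np.cos(ang + phases[i])
            vy = centers[i, 1] + r0[i] * scale * np.sin(ang + phases[i])
            rows.append(pd.DataFrame({
                "cell_id": i, "frame": f, "vertex_index": np.arange(k),
                "x_um": vx, "y_um": vy,
            }))
            truth.append({"cell_id": i, "frame": f,
                          "true_area_um2": area0[i] * scale**2,
                          "init_dist_um": d0[i]})
    return ShapeSeries(
        vertices=pd.concat(rows, ignore_index=True),
        reference=ref,
        truth=pd.DataFrame(truth),
    )


def shrink_polygon_series(vertices, factor: float, n_frames: int) -> list[np.ndarray]:
    """Scale a polygon about its centroid by ``factor`` per frame; frame 0
    is the input polygon.  Areas follow factor**(2*frame)."""
    if factor <= 0:
        raise ValueError("shrink factor must be > 0")
    v = np.asarray(vertices, dtype=float)
    from tissuekin.morphometrics import polygon_centroid
    c = polygon_centroid(v)
    return [c + (v[:, :2] - c) * factor**f for f in range(n_frames)]
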