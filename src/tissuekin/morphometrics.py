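"""Constriction morphometrics: cell areas vs distance, density bands and
division-plane statistics.

Cells approaching a constricting midline shrink and crowd; these routines
quantify that from segmented outlines (polygon vertex tables), centroid
positions and division events, relative to a reference point on the midline
(for the dorsal pericardium, near the atrio-ventricular canal) and the
midline itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from tissuekin.midline import Midline


# --------------------------------------------------------------------------
# polygons

def polygon_area(vertices) -> float:
    """Area (µm²) of a simple polygon from its ordered vertices,
    independent of orientation.  Self-intersecting input is rejected."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 2:
        raise ValueError("polygon needs >= 3 ordered 2D vertices")
    poly = Polygon(v[:, :2])
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    return float(poly.area)


def polygon_centroid(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    c = Polygon(v[:, :2]).centroid
    return np.array([c.x, c.y])


@dataclass
class ShapeSeries:
    """Per-cell per-frame polygon outlines with a reference point.

    ``vertices`` has columns cell_id, frame, vertex_index, x_um, y_um;
    ``reference`` is the 2D/3D reference point (only xy is used).
    Optional ``true_area`` column on measurement tables carries generator
    ground truth.
    """

    vertices: pd.DataFrame
    reference: np.ndarray
    truth: Optional[pd.DataFrame] = None  # generator ground truth, if synthetic

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float).reshape(-1)[:2]
        need = {"cell_id", "frame", "vertex_index", "x_um", "y_um"}
        missing = need - set(self.vertices.columns)
        if missing:
            raise ValueError(f"shape table missing column(s): {sorted(missing)}")

    def measurements(self) -> pd.DataFrame:
        """Area, centroid and distance-to-reference per cell per frame."""
        rows = []
        for (cid, fr), g in self.vertices.groupby(["cell_id", "frame"], sort=True):
            v = g.sort_values("vertex_index")[["x_um", "y_um"]].to_numpy(float)
            a = polygon_area(v)
            c = polygon_centroid(v)
            rows.append({
                "cell_id": cid, "frame": fr, "area_um2": a,
                "cx_um": c[0], "cy_um": c[1],
                "dist_um": float(np.hypot(*(c - self.reference))),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.vertices.to_csv(path, index=False)


# --------------------------------------------------------------------------
# distance categories and area profiles

@dataclass(frozen=True)
class DistanceCategory:
    """Half-open distance band (lower, upper] in µm; the innermost band
    also contains distance 0 (closed lower bound at zero)."""

    label: str
    lower: float
    upper: float

    def contains(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.lower <= 0:
            return (d >= 0) & (d <= self.upper)
        return (d > self.lower) & (d <= self.upper)


def default_distance_categories() -> list[DistanceCategory]:
    """The standard three bands by initial distance to the reference point:
    up to 50 µm, 50-150 µm, beyond 150 µm (boundary values go to the
    nearer band: closed upper bounds)."""
    return [
        DistanceCategory("<=50um", 0.0, 50.0),
        DistanceCategory("50-150um", 50.0, 150.0),
        DistanceCategory(">150um", 150.0, np.inf),
    ]


def area_distance_profile(
    shapes: ShapeSeries,
    categories: Optional[Sequence[DistanceCategory]] = None,
) -> dict:
    """Mean ± s.d. of cell area and distance per frame, per distance band.

    Each cell is assigned once, by its FIRST-frame distance to the
    reference.  Returns ``per_frame`` (frame, category, n, mean/sd of area
    and distance) and ``slopes`` (least-squares slope of mean area vs frame
    per category, with its sign as the trend statistic).  Bands with no
    cells are absent from the tables.
    """
    categories = list(categories) if categories is not None else default_distance_categories()
    meas = shapes.measurements()
    first = meas.sort_values("frame").groupby("cell_id").first()
    assign = {}
    for cid, row in first.iterrows():
        for cat in categories:
            if cat.contains(row["dist_um"]):
                assign[cid] = cat.label
                break
    meas = meas.assign(category=meas["cell_id"].map(assign))
    meas = meas[meas["category"].notna()]
    per_frame = (
        meas.groupby(["frame", "category"])
        .agg(n=("area_um2", "size"),
             mean_area_um2=("area_um2", "mean"), sd_area_um2=("area_um2", "std"),
             mean_dist_um=("dist_um", "mean"), sd_dist_um=("dist_um", "std"))
        .reset_index()
    )
    slopes = []
    for cat in categories:
        sub = per_frame[per_frame["category"] == cat.label]
        if len(sub) == 0:
            continue
        if len(sub) == 1:
            slope = 0.0
        else:
            slope = float(np.polyfit(sub["frame"], sub["mean_area_um2"], 1)[0])
        slopes.append({"category": cat.label, "slope_um2_per_frame": slope,
                       "trend_sign": int(np.sign(slope))})
    return {"per_frame": per_frame, "slopes": pd.DataFrame(slopes),
            "assignment": assign}


# --------------------------------------------------------------------------
# cell density bands

def cell_density(
    positions,
    reference,
    radii: Sequence[float] = (70.0, 100.0),
    excluded: Optional[Polygon] = None,
    hull: Optional[Polygon] = "auto",
) -> pd.DataFrame:
    """Cell density (cells/µm²) in concentric distance bands around the
    reference point: within r1, (r1, r2], beyond r2.

    Band areas are geometric (disk / annulus) minus any overlap with the
    ``excluded`` polygon (e.g. a region obscured by the heart tube, whose
    cells are also excluded from the counts).  The unbounded outer band is
    clipped to the convex hull of the data (``hull='auto'``) or a given
    polygon.  A band whose area vanishes after exclusion is returned with
    NaN density.
    """
    P = np.atleast_2d(np.asarray(positions, dtype=float))[:, :2]
    ref = np.asarray(reference, dtype=float).reshape(-1)[:2]
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
        raise ValueError("radii must be positive and strictly increasing")
    d = np.hypot(P[:, 0] - ref[0], P[:, 1] - ref[1])
    if excluded is not None:
        inside_excl = np.array([excluded.covers(Point(*p)) for p in P])
    else:
        inside_excl = np.zeros(len(P), dtype=bool)

    qs = 256  # circle discretization for band geometry
    disks = [Point(*ref).buffer(r, quad_segs=qs) for r in radii]
    bands = [disks[0]]
    for inner, outer in zip(disks[:-1], disks[1:]):
        bands.append(outer.difference(inner))
    if hull == "auto":
        hull = MultiPoint([tuple(p) for p in P]).convex_hull
    if hull is None:
        raise ValueError("outer band requires a hull polygon (or 'auto')")
    bands.append(hull.difference(disks[-1]))

    edges = [0.0] + radii + [np.inf]
    labels = [f"<= {radii[0]:g} um"]
    labels += [f"{a:g}-{b:g} um" for a, b in zip(radii[:-1], radii[1:])]
    labels += [f"> {radii[-1]:g} um"]

    rows = []
    for i, (geom, label) in enumerate(zip(bands, labels)):
        lo, hi = edges[i], edges[i + 1]
        in_band = (d > lo) & (d <= hi) if lo > 0 else (d <= hi)
        count = int(np.sum(in_band & ~inside_excl))
        area = geom.area
        if excluded is not None:
            area -= geom.intersection(excluded).area
        rows.append({
            "band": label, "lower_um": lo, "upper_um": hi, "count": count,
            "area_um2": area,
            "density_per_um2": count / area if area > 1e-9 else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# division planes

@dataclass(frozen=True)
class DivisionEvent:
    """A mitosis with its division-plane orientation relative to the
    midline: ``angle_deg`` is the plane-to-midline angle folded to
    [0°, 90°]; class 'perpendicular' covers 45°-90° (45° inclusive),
    'parallel' covers 0°-45°."""

    t_s: float
    position: np.ndarray
    plane_dir: np.ndarray
    angle_deg: float
    distance_um: float
    cls: str


def classify_division_angle(angle_deg: float) -> str:
    if not (0.0 <= angle_deg <= 90.0):
        raise ValueError(f"division-plane angle {angle_deg} outside [0, 90]")
    return "perpendicular" if angle_deg >= 45.0 else "parallel"


def _fold90(theta_deg: float) -> float:
    t = theta_deg % 180.0
    return min(t, 180.0 - t)


def division_plane_metrics(
    midline: Midline,
    position=None,
    plane_dir=None,
    daughters=None,
    t: float = 0.0,
    mode: str = "3d",
) -> DivisionEvent:
    """Angle and distance of a division plane to the midline.

    The plane may be given directly as its in-surface line direction
    (``plane_dir``), or derived from the two daughter-cell positions: the
    division plane is perpendicular to the daughter-separation axis, so its
    angle to the midline is 90° minus the axis-to-midline angle (daughters
    separating along the midline mean a plane perpendicular to it).
    ``position`` defaults to the daughter midpoint.
    """
    u = midline.direction(mode)
    if daughters is not None:
        d0, d1 = (np.asarray(x, dtype=float).reshape(3) for x in daughters)
        axis = d1 - d0
        if np.linalg.norm(axis) == 0:
            raise ValueError("coincident daughter positions: plane direction undefined")
        if position is None:
            position = (d0 + d1) / 2.0
        axis_angle = _fold90(np.degrees(np.arccos(
            np.clip(abs((axis / np.linalg.norm(axis)) @ u), 0.0, 1.0))))
        angle = 90.0 - axis_angle
        # report an in-plane (xy) direction of the plane line for the record
        pd_xy = np.array([-axis[1], axis[0], 0.0])
        n = np.linalg.norm(pd_xy)
        plane_vec = pd_xy / n if n > 0 else np.array([np.nan] * 3)
    elif plane_dir is not None:
        plane_vec = np.asarray(plane_dir, dtype=float).reshape(3)
        n = np.linalg.norm(plane_vec)
        if n == 0:
            raise ValueError("zero plane direction")
        plane_vec = plane_vec / n
        angle = _fold90(np.degrees(np.arccos(np.clip(abs(plane_vec @ u), 0.0, 1.0))))
        if position is None:
            raise ValueError("position required when plane_dir is given")
    else:
        raise ValueError("give either plane_dir or daughters")
    position = np.asarray(position, dtype=float).reshape(3)
    dist = float(midline.distance_to(position.reshape(1, 3), mode)[0])
    return DivisionEvent(
        t_s=float(t), position=position, plane_dir=plane_vec,
        angle_deg=float(angle), distance_um=dist,
        cls=classify_division_angle(float(angle)),
    )


def divisions_table(events: Iterable[DivisionEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "t_s": e.t_s, "x_um": e.position[0], "y_um": e.position[1],
        "z_um": e.position[2], "plane_dir_x": e.plane_dir[0],
        "plane_dir_y": e.plane_dir[1], "plane_dir_z": e.plane_dir[2],
        "angle_deg": e.angle_deg, "distance_um": e.distance_um, "cls": e.cls,
    } for e in events])


def division_distance_distribution(events: pd.DataFrame, bin_edges) -> dict:
    """Histogram of division distances to the midline, plus the paired
    (distance, angle) table for distance-vs-orientation scatter.

    Bins are right-closed, (lo, hi]; a distance equal to an interior edge
    counts in the lower bin, and a distance equal to the first edge counts
    in the first bin.  Counts are conserved for all in-range events.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must strictly increase")
    d = events["distance_um"].to_numpy(dtype=float)
    idx = np.searchsorted(edges, d, side="left") - 1
    idx[d == edges[0]] = 0
    counts = np.zeros(len(edges) - 1, dtype=int)
    in_range = (idx >= 0) & (idx < len(counts)) & (d <= edges[-1]) & (d >= edges[0])
    np.add.at(counts, idx[in_range], 1)
    hist = pd.DataFrame({
        "lower_um": edges[:-1], "upper_um": edges[1:], "count": counts,
    })
    pairs_cols = ["distance_um", "angle_deg"] + (["cls"] if "cls" in events else [])
    return {"histogram": hist, "pairs": events[pairs_cols].copy(),
            "n_out_of_range": int(np.sum(~in_range))}
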