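"""Midline geometry and trajectory directionality.

The midline is the anatomical reference axis of the tissue — for the dorsal
pericardium it runs from the venous pole (A) to the arterial pole / outflow
tract (B).  Trajectory orientation is reported as the angle between a cell's
net displacement vector and the A->B direction, on the half-rose convention
[0°, 180°]; directionality ("towards" / "away" / "neutral") compares the
perpendicular distances of the first and last track point to the midline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tie tolerance (µm) below which a distance change counts as "neutral"
DEFAULT_D_EPS = 1e-6


@dataclass(frozen=True)
class Midline:
    """Oriented reference line from point ``a`` (venous pole) to ``b``
    (arterial pole), in µm.  Distances are measured to the infinite line
    through ``a`` and ``b`` unless ``clamp`` is requested."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float).reshape(3)
        b = np.asarray(self.b, dtype=float).reshape(3)
        if np.allclose(a, b):
            raise ValueError("midline endpoints must differ")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def direction(self, mode: str = "3d") -> np.ndarray:
        """Unit vector from a to b; for ``mode='xy'`` the xy projection."""
        d = self.b - self.a
        if mode == "xy":
            d = np.array([d[0], d[1], 0.0])
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("midline direction degenerate in this projection")
        return d / n

    def distance_to(self, points, mode: str = "3d", clamp: bool = False) -> np.ndarray:
        """Perpendicular distance (µm) from each point to the midline.

        mode='3d' uses full 3D distance to the line; mode='xy' projects
        points and line into the xy plane first.  ``clamp=True`` measures to
        the segment a-b instead of the infinite line.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a, b = self.a.copy(), self.b.copy()
        if mode == "xy":
            p = p.copy()
            p[:, 2] = 0.0
            a[2] = b[2] = 0.0
        u = b - a
        uu = u @ u
        tpar = ((p - a) @ u) / uu
        if clamp:
            tpar = np.clip(tpar, 0.0, 1.0)
        foot = a[None, :] + tpar[:, None] * u[None, :]
        return np.linalg.norm(p - foot, axis=1)

    def perpendicular_offset(self, points, mode: str = "xy") -> np.ndarray:
        """Vector from the line's nearest point to each point (z zeroed for
        mode='xy').  Used by flow fields that converge on the midline."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a, b = self.a.copy(), self.b.copy()
        if mode == "xy":
            pp = p.copy()
            pp[:, 2] = 0.0
            a[2] = b[2] = 0.0
        else:
            pp = p
        u = b - a
        tpar = ((pp - a) @ u) / (u @ u)
        foot = a[None, :] + tpar[:, None] * u[None, :]
        off = pp - foot
        if mode == "xy":
            off[:, 2] = 0.0
        return off


def angle_to_midline(displacement, midline: Midline, mode: str = "3d") -> float:
    """Angle (degrees, [0, 180]) between a net-displacement vector and the
    midline's A->B direction.

    Raises ValueError for a zero displacement (angle undefined).
    """
    d = np.asarray(displacement, dtype=float).reshape(-1)
    if d.size == 2:
        d = np.array([d[0], d[1], 0.0])
    if mode == "xy":
        d = np.array([d[0], d[1], 0.0])
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("zero net displacement: angle to midline undefined")
    u = midline.direction(mode)
    c = float(np.clip((d / nd) @ u, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def classify_directionality(
    first_point,
    last_point,
    midline: Midline,
    mode: str = "3d",
    d_eps: float = DEFAULT_D_EPS,
) -> str:
    """'towards' if the track ends closer to the midline than it started,
    'away' if farther, 'neutral' if the change is within ``d_eps`` µm."""
    d0 = float(midline.distance_to(np.asarray(first_point, float).reshape(1, 3), mode)[0])
    d1 = float(midline.distance_to(np.asarray(last_point, float).reshape(1, 3), mode)[0])
    if d0 - d1 > d_eps:
        return "towards"
    if d1 - d0 > d_eps:
        return "away"
    return "neutral"


def track_summaries(
    ts,
    midline: Midline,
    mode: str = "3d",
    d_eps: float = DEFAULT_D_EPS,
) -> pd.DataFrame:
    """Per-track net displacement, angle to midline and directionality class.

    Tracks with zero net displacement get angle NaN (they still classify,
    normally as 'neutral').  Columns: track_id, x0..z0, x1..z1, disp_um,
    angle_deg, dist_first_um, dist_last_um, direction.
    """
    rows = []
    for tid, g in ts.df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        p0 = g[["x_um", "y_um", "z_um"]].iloc[0].to_numpy(float)
        p1 = g[["x_um", "y_um", "z_um"]].iloc[-1].to_numpy(float)
        disp = p1 - p0
        nd = float(np.linalg.norm(disp if mode == "3d" else disp[:2]))
        try:
            ang = angle_to_midline(disp, midline, mode)
        except ValueError:
            ang = np.nan
        rows.append(
            {
                "track_id": tid,
                "x0_um": p0[0], "y0_um": p0[1], "z0_um": p0[2],
                "x1_um": p1[0], "y1_um": p1[1], "z1_um": p1[2],
                "disp_um": nd,
                "angle_deg": ang,
                "dist_first_um": float(midline.distance_to(p0.reshape(1, 3), mode)[0]),
                "dist_last_um": float(midline.distance_to(p1.reshape(1, 3), mode)[0]),
                "direction": classify_directionality(p0, p1, midline, mode, d_eps),
            }
        )
    out = pd.DataFrame(rows)
    n_excl = int(out["angle_deg"].isna().sum()) if len(out) else 0
    if n_excl:
        logger.info("track_summaries: %d track(s) with zero net displacement (angle undefined)", n_excl)
    return out


def rose_histogram(angles, bin_width: float) -> pd.DataFrame:
    """Half-rose angular histogram over [0°, 180°).

    ``bin_width`` must divide 180.  Bins are left-closed; an angle of exactly
    180° is counted in the last bin so the total is conserved.  Returns a
    DataFrame with bin_start_deg, bin_end_deg, count.
    """
    if bin_width <= 0 or abs(180.0 / bin_width - round(180.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 180")
    a = np.asarray([x for x in np.atleast_1d(angles) if np.isfinite(x)], dtype=float)
    nbins = int(round(180.0 / bin_width))
    edges = np.linspace(0.0, 180.0, nbins + 1)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame(
        {"bin_start_deg": edges[:-1], "bin_end_deg": edges[1:], "count": counts}
    )


def directionality_fractions(
    ts,
    midline: Midline,
    mode: str = "3d",
    d_eps: float = DEFAULT_D_EPS,
) -> dict:
    """Percentages of tracks moving towards / away from / neutral to the
    midline, over all classifiable tracks (sums to 100)."""
    summ = track_summaries(ts, midline, mode, d_eps)
    if len(summ) == 0:
        raise ValueError("no classifiable tracks")
    counts = summ["direction"].value_counts()
    n = int(len(summ))
    return {
        "towards_pct": 100.0 * counts.get("towards", 0) / n,
        "away_pct": 100.0 * counts.get("away", 0) / n,
        "neutral_pct": 100.0 * counts.get("neutral", 0) / n,
        "n_classified": n,
    }
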