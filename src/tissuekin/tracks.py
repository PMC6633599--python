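"""Track table ingestion, filtering, drift correction and velocities.

The canonical on-disk format is a CSV with header
``track_id,frame,t_s,x_um,y_um,z_um``.  A column map lets Imaris-style
exports ("TrackID", "Time", "Position X" ...) load without editing the file,
with optional unit conversion for time (e.g. ms -> s) and length
(mm -> µm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "z_um"]

#: fractional tolerance on frame-interval constancy
FRAME_INTERVAL_RTOL = 0.01


@dataclass
class TrackSet:
    """Validated 4D trajectories sharing one frame clock.

    ``df`` holds one row per (track_id, frame) with columns
    ``track_id, frame, t_s, x_um, y_um, z_um``; synthetic sets may carry
    extra ``gt_*_um`` ground-truth columns and a ``truncated`` flag.
    """

    df: pd.DataFrame
    frame_interval: float

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track table missing column(s): {missing}")
        df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
        dup = df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            pairs = df.loc[dup, ["track_id", "frame"]].values.tolist()
            raise ValueError(f"duplicate (track_id, frame) pair(s): {pairs[:5]}")
        interval = _validate_frame_clock(df)
        return cls(df=df, frame_interval=interval)

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())

    @property
    def n_points(self) -> int:
        return int(len(self.df))

    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    def track_ids(self):
        return list(self.df["track_id"].unique())

    def positions(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _validate_frame_clock(df: pd.DataFrame) -> float:
    """Frames and times must strictly increase within tracks and imply one
    constant frame interval (within 1%)."""
    rates = []
    for tid, g in df.groupby("track_id", sort=False):
        f = g["frame"].to_numpy()
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError(f"track {tid!r}: frames not strictly increasing")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {tid!r}: times not strictly increasing")
        if len(f) > 1:
            rates.append(np.diff(t) / np.diff(f))
    if not rates:
        # single-point tracks only; no interval derivable
        return float("nan")
    r = np.concatenate(rates)
    med = float(np.median(r))
    if np.any(np.abs(r - med) > FRAME_INTERVAL_RTOL * med):
        raise ValueError(
            f"inconsistent frame interval: median {med:g} s/frame but observed "
            f"range [{r.min():g}, {r.max():g}]"
        )
    return med


def read_tracks(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    time_scale: float = 1.0,
    length_scale: float = 1.0,
    sep: str = ",",
) -> TrackSet:
    """Read a delimited track table.

    ``column_map`` maps the canonical keys ``track_id, frame, t, x, y, z`` to
    the file's column names (defaults to the canonical header).  ``time_scale``
    and ``length_scale`` are multipliers applied to reach seconds / µm.
    Rows with non-numeric coordinates are dropped with a logged count.
    """
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cmap = {"track_id": "track_id", "frame": "frame", "t": "t_s",
            "x": "x_um", "y": "y_um", "z": "z_um"}
    if column_map:
        cmap.update(column_map)
    for key, col in cmap.items():
        if col not in raw.columns:
            raise ValueError(f"mapped column {col!r} (for {key!r}) not in file {path}")
    df = pd.DataFrame({
        "track_id": raw[cmap["track_id"]],
        "frame": raw[cmap["frame"]],
        "t_s": pd.to_numeric(raw[cmap["t"]], errors="coerce") * time_scale,
        "x_um": pd.to_numeric(raw[cmap["x"]], errors="coerce") * length_scale,
        "y_um": pd.to_numeric(raw[cmap["y"]], errors="coerce") * length_scale,
        "z_um": pd.to_numeric(raw[cmap["z"]], errors="coerce") * length_scale,
    })
    bad = df[["t_s", "x_um", "y_um", "z_um"]].isna().any(axis=1)
    if bad.any():
        logger.warning("read_tracks: dropped %d row(s) with non-numeric fields", int(bad.sum()))
        df = df[~bad]
    df["frame"] = df["frame"].astype(int)
    return TrackSet.from_dataframe(df)


def write_tracks(ts: TrackSet, path) -> None:
    """Write the canonical CSV (extra columns preserved); floats are
    written with round-trip precision so read∘write is lossless."""
    ts.df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class FilterCounts:
    n_input: int
    n_retained: int
    n_removed: int


def filter_tracks(
    ts: TrackSet,
    min_duration: int = 10,
    min_displacement: float = 5.0,
) -> tuple[TrackSet, FilterCounts]:
    """Keep tracks with at least ``min_duration`` frames AND a net
    (straight-line, first-to-last) displacement of at least
    ``min_displacement`` µm — removing short or stationary false-positive
    trajectories before any kinematic analysis."""
    if min_duration < 0 or min_displacement < 0:
        raise ValueError("filter thresholds must be >= 0")
    keep = []
    for tid, g in ts.df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        p0 = g[["x_um", "y_um", "z_um"]].iloc[0].to_numpy(float)
        p1 = g[["x_um", "y_um", "z_um"]].iloc[-1].to_numpy(float)
        if len(g) >= min_duration and np.linalg.norm(p1 - p0) >= min_displacement:
            keep.append(tid)
    out = ts.df[ts.df["track_id"].isin(keep)].reset_index(drop=True)
    counts = FilterCounts(ts.n_tracks, len(keep), ts.n_tracks - len(keep))
    if len(out) == 0:
        empty = TrackSet(df=out, frame_interval=ts.frame_interval)
        return empty, counts
    return TrackSet.from_dataframe(out), counts


def correct_drift(ts: TrackSet, reference_track_id) -> TrackSet:
    """Subtract the displacement of a stable reference track from every
    point, frame by frame.

    The reference (e.g. a tracked stable anatomical structure such as the
    venous pole) must span every frame of the set; afterwards it is
    stationary at its frame-0 position and inter-cell relative positions in
    each frame are unchanged.
    """
    ref = ts.df[ts.df["track_id"] == reference_track_id].sort_values("frame")
    if len(ref) == 0:
        raise ValueError(f"reference track {reference_track_id!r} not in track set")
    frames = ts.frames()
    missing = sorted(int(f) for f in set(frames) - set(ref["frame"]))
    if missing:
        raise ValueError(
            f"reference track {reference_track_id!r} missing frame(s): {missing}"
        )
    ref0 = ref[["x_um", "y_um", "z_um"]].iloc[0].to_numpy(float)
    shift = ref.set_index("frame")[["x_um", "y_um", "z_um"]] - ref0
    df = ts.df.copy()
    sh = shift.loc[df["frame"]].to_numpy()
    df[["x_um", "y_um", "z_um"]] = df[["x_um", "y_um", "z_um"]].to_numpy() - sh
    return TrackSet.from_dataframe(df)


def estimate_velocities(ts: TrackSet, scheme: str = "forward") -> pd.DataFrame:
    """Per-point velocities in µm/s.

    scheme='forward' (default): one sample per consecutive frame pair,
    v = (x_{t+1} - x_t) / Δt, indexed by the earlier frame but anchored at
    the frame-pair midpoint position and time.  Midpoint anchoring makes
    the sample's position error independent of its velocity error under
    i.i.d. tracking noise (anchoring at the earlier frame correlates them
    with covariance -σ²/Δt, which systematically dilutes downstream
    velocity gradients) and is second-order accurate for smooth motion.
    scheme='central' anchors at interior points with
    v = (x_{i+1} - x_{i-1}) / (t_{i+1} - t_{i-1}).
    """
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown differencing scheme {scheme!r}")
    out = []
    for tid, g in ts.df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        t = g["t_s"].to_numpy(float)
        P = g[["x_um", "y_um", "z_um"]].to_numpy(float)
        f = g["frame"].to_numpy()
        if len(g) < 2:
            continue
        if scheme == "forward":
            dt = np.diff(t)
            V = np.diff(P, axis=0) / dt[:, None]
            anchor = (P[:-1] + P[1:]) / 2.0
            tmid = t[:-1] + dt / 2.0
            fr = f[:-1]
        else:
            if len(g) < 3:
                continue
            dt = t[2:] - t[:-2]
            V = (P[2:] - P[:-2]) / dt[:, None]
            anchor = P[1:-1]
            tmid = t[1:-1]
            fr = f[1:-1]
        out.append(pd.DataFrame({
            "track_id": tid, "frame": fr, "t_s": tmid,
            "x_um": anchor[:, 0], "y_um": anchor[:, 1], "z_um": anchor[:, 2],
            "vx_um_s": V[:, 0], "vy_um_s": V[:, 1], "vz_um_s": V[:, 2],
        }))
    if not out:
        return pd.DataFrame(columns=["track_id", "frame", "t_s", "x_um", "y_um",
                                     "z_um", "vx_um_s", "vy_um_s", "vz_um_s"])
    return pd.concat(out, ignore_index=True)
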