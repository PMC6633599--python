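"""End-to-end orchestration: ingestion -> kinematics -> reports.

``run_pipeline`` reads (or generates) tracks, filters and drift-corrects
them, computes the surface divergence series and midline directionality,
optionally the shape/division morphometrics, and writes CSV tables plus a
machine-readable ``summary.json``.  Given the same config and seed the
summary is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from tissuekin import __version__
from tissuekin.config import RunConfig
from tissuekin.divergence import divergence_series
from tissuekin.midline import directionality_fractions, rose_histogram, track_summaries
from tissuekin.morphometrics import (
    ShapeSeries,
    area_distance_profile,
    cell_density,
    division_distance_distribution,
    division_plane_metrics,
    divisions_table,
)
from tissuekin.synthetic import generate_tracks
from tissuekin.tracks import correct_drift, filter_tracks, read_tracks, write_tracks

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tissuekin")
    root.addHandler(fh)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {"tool_version": __version__, "config": config.echo()}
    try:
        stage = "ingest"
        if config.scene is not None:
            ts = generate_tracks(config.scene)
        elif config.tracks_path:
            ts = read_tracks(config.tracks_path, config.column_map,
                             config.time_scale, config.length_scale)
        else:
            raise ValueError("config must give tracks_path or scene")
        summary["n_tracks_input"] = ts.n_tracks
        summary["n_points_input"] = ts.n_points

        stage = "filter"
        if config.filter_enabled:
            ts, counts = filter_tracks(ts, config.min_duration, config.min_displacement)
            summary["filter"] = {"retained": counts.n_retained,
                                 "removed": counts.n_removed}
            if counts.n_retained == 0:
                raise ValueError("no tracks retained after filtering")

        stage = "drift"
        if config.drift_reference is not None:
            ts = correct_drift(ts, config.drift_reference)
            summary["drift_reference"] = config.drift_reference

        write_tracks(ts, out / "tracks_used.csv")
        midline = config.midline()

        stage = "divergence"
        res = divergence_series(ts, config.divergence, midline)
        res.to_csv(out / "divergence_nodes.csv", out / "divergence_means.csv")
        summary["divergence"] = {
            "grand_mean_per_s": res.grand_mean,
            "grand_sd_per_s": res.grand_sd,
            "grand_mean_per_frame": res.grand_mean * ts.frame_interval,
            "n_frame_pairs": int(len(res.frame_means)),
            "skipped_frames": res.skipped_frames,
        }

        stage = "midline_kinematics"
        summ = track_summaries(ts, midline, config.directionality_mode, config.d_eps)
        summ.to_csv(out / "track_summary.csv", index=False)
        rose = rose_histogram(summ["angle_deg"].dropna(), config.rose_bin_width)
        rose.to_csv(out / "rose.csv", index=False)
        fracs = directionality_fractions(ts, midline, config.directionality_mode,
                                         config.d_eps)
        summary["directionality"] = fracs
        summary["n_angle_excluded"] = int(summ["angle_deg"].isna().sum())

        stage = "morphometrics"
        if config.shapes_path:
            if config.reference_point is None:
                raise ValueError("shapes analysis requires reference_point")
            vertices = pd.read_csv(config.shapes_path)
            shapes = ShapeSeries(vertices=vertices, reference=np.asarray(config.reference_point))
            prof = area_distance_profile(shapes)
            prof["per_frame"].to_csv(out / "area_profile.csv", index=False)
            prof["slopes"].to_csv(out / "area_slopes.csv", index=False)
            meas = shapes.measurements()
            last = meas[meas["frame"] == meas["frame"].max()]
            dens = cell_density(last[["cx_um", "cy_um"]].to_numpy(),
                                np.asarray(config.reference_point)[:2],
                                config.density_radii)
            dens.to_csv(out / "density.csv", index=False)
            summary["area_slopes"] = {
                r["category"]: r["slope_um2_per_frame"]
                for r in prof["slopes"].to_dict("records")
            }
        if config.divisions_path:
            raw = pd.read_csv(config.divisions_path)
            events = [
                division_plane_metrics(
                    midline,
                    position=np.array([r["x_um"], r["y_um"], r["z_um"]]),
                    plane_dir=np.array([r["plane_dir_x"], r["plane_dir_y"],
                                        r["plane_dir_z"]]),
                    t=r.get("t_s", 0.0),
                )
                for r in raw.to_dict("records")
            ]
            tbl = divisions_table(events)
            tbl.to_csv(out / "divisions.csv", index=False)
            dist = division_distance_distribution(tbl, [0, 25, 50, 75, 100, 150, 300])
            dist["histogram"].to_csv(out / "division_distance_hist.csv", index=False)
            summary["divisions"] = {
                "n": int(len(tbl)),
                "perpendicular": int((tbl["cls"] == "perpendicular").sum()),
                "parallel": int((tbl["cls"] == "parallel").sum()),
            }
    except Exception as e:  # noqa: BLE001 - reported with failing stage
        (out / "FAILED").write_text(f"stage {stage}: {e}\n")
        root.removeHandler(fh)
        raise PipelineError(stage, e) from e

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True, default=float)
        f.write("\n")
    root.removeHandler(fh)
    fh.close()
    return summary
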