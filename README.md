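# tissuekin

Tissue kinematics from 4D cell tracks: divergence fields on curved
monolayers, midline directionality, and constriction morphometrics.

## Who this is for

Developmental and cell biologists quantifying collective cell movements in
epithelial or mesothelial monolayers from time-lapse tracking data — for
example the zebrafish dorsal pericardium, where cells converge on a midline
running between the venous and arterial poles of the heart tube, constrict,
and extrude to form the proepicardium. The package consumes exported track
tables (canonical CSV or Imaris-style `Position X/Y/Z` columns via a column
map), midline endpoints, and optionally cell-outline polygons and division
events; it produces per-node divergence maps, per-frame mean divergence,
rose histograms of trajectory angles, towards/away fractions, cell-area and
density profiles, and division-plane statistics.

## The model

The monolayer is a laminar 2D surface embedded in 3D, z = f(x, y). Per
frame pair, track displacements give a sampled velocity field
v = (v_x, v_y, v_z) in µm/s. A regular grid with spacing Δx_grid below
twice the nucleus size carries the surface height (piecewise-linear
interpolation over the Delaunay triangulation of the cell positions) and
the velocity components (thin-plate smoothing splines). The 2D divergences
in the xy, yz and xz planes are taken by finite differences along grid
lines and combined as

    ∇·v = (D_xy + D_yz + D_xz) / 2
        = ∂v_x/∂x + ∂v_y/∂y + ∂v_z/∂z ,

each partial appearing in exactly two planes. Negative nodal values mean
local constriction, positive expansion; the unweighted mean over the valid
surface S summarizes each frame, and the series over frames gives the
grand mean ± s.d. Trajectory directionality compares the perpendicular
distance of a track's first and last point to the midline (closer at the
end ⇒ "towards"); trajectory angles against the midline direction are
binned on the half-rose [0°, 180°]. Division planes are classified
perpendicular (45° ≤ α ≤ 90°) or parallel (α < 45°) to the midline.

A synthetic-scene generator with analytically known kinematics (prescribed
flows on flat or gently curved surfaces, tracking noise, divisions, shrinking
cell shapes) backs every stage with exact ground truth; see
`docs/methods.md` for the numerical choices and their rationale.

## Worked example

Generate the reference scene — 150 cells over 43 frames at 12-min
intervals, converging on the y-axis midline at k = 2×10⁻⁵ s⁻¹ with a
constriction hotspot on the midline and 1 µm tracking noise — and run the
full analysis:

```python
from tissuekin import (generate_tracks, filter_tracks, divergence_series,
                       directionality_fractions, rose_histogram, track_summaries)
from tissuekin.specs import default_convergence_scene
from tissuekin.divergence import DivergenceParams
from tissuekin.midline import Midline

midline = Midline((0, -150, 0), (0, 150, 0))   # venous pole -> arterial pole
scene = default_convergence_scene(k=2e-5, seed=1)
tracks = generate_tracks(scene)
tracks, counts = filter_tracks(tracks, min_duration=10, min_displacement=5.0)
print(f"tracks retained: {counts.n_retained}/{counts.n_input}")

result = divergence_series(tracks, DivergenceParams(smoothing=300.0), midline)
print(f"mean divergence: {result.grand_mean:.2e} +/- {result.grand_sd:.2e} s^-1")
near = (result.frame_means["min_dist_to_midline_um"]
        <= 2 * result.frame_means["grid_spacing_um"]).mean()
print(f"constriction hotspot at midline in {100*near:.0f}% of frames")

fractions = directionality_fractions(tracks, midline)
print(f"towards midline: {fractions['towards_pct']:.1f}% of {fractions['n_classified']} tracks")

angles = track_summaries(tracks, midline)["angle_deg"].dropna()
rose = rose_histogram(angles, 15.0)
top = rose.loc[rose["count"].idxmax()]
print(f"modal trajectory angle bin: {top.bin_start_deg:.0f}-{top.bin_end_deg:.0f} deg "
      f"({int(top['count'])} tracks)")
```

Output:

```
tracks retained: 144/150
mean divergence: -1.94e-05 +/- 5.98e-06 s^-1
constriction hotspot at midline in 93% of frames
towards midline: 100.0% of 144 tracks
modal trajectory angle bin: 90-105 deg (72 tracks)
```

The grand-mean divergence recovers the prescribed −2×10⁻⁵ s⁻¹ within a few
percent despite the tracking noise; the most negative node sits at the
midline in nearly every frame; every retained track moves towards the
midline; and the modal trajectory angle is ~90°, i.e. cells move nearly
perpendicular to the midline — the kinematic signature of a monolayer
constricting onto its midline.

### Command line

```sh
tkin synth tracks --config scene.yaml --seed 1 --out scene_out/
tkin divfield --tracks scene_out/tracks.csv --config scene.yaml --out div_out/
tkin run --config run.yaml          # full pipeline from one config
```

`tkin run` writes `tracks_used.csv`, `divergence_nodes.csv`,
`divergence_means.csv`, `track_summary.csv`, `rose.csv`, a `run.log`, and a
machine-readable `summary.json` that is byte-identical across reruns of the
same config and seed.

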