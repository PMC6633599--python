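# Methods

`tissuekin` quantifies collective cell rearrangements in a curved epithelial
or mesothelial monolayer from 4D cell-track tables. Its centerpiece is a
divergence-field calculator for the tissue velocity field evaluated on an
interpolated surface, flanked by trajectory directionality relative to an
anatomical midline and constriction morphometrics (cell areas, densities,
division-plane orientations). This note records the model, the numerical
choices and their rationale, what the synthetic scenes do and do not emulate,
and the known limitations.

## The divergence model

The monolayer is treated as a laminar 2D surface embedded in 3D, described
by a single-valued height field z = f(x, y). Per consecutive frame pair:

1. **Velocities.** v = Δx/Δt per track over the frame pair, in µm/s. The
   sample is indexed by the earlier frame but anchored at the *midpoint*
   position and time of the pair. Midpoint anchoring matters under tracking
   noise: anchoring at the earlier frame makes a sample's position error and
   velocity error correlated (covariance −σ²/Δt), which systematically
   dilutes every fitted velocity gradient downstream; at the midpoint the
   two errors are independent, and the scheme is second-order accurate for
   smooth motion.
2. **Grid.** A regular xy lattice over the bounding box of the samples with
   spacing Δx_grid = nucleus size by default, hard-capped just below twice
   the nucleus size (the sampling bound for nucleus-scale features; nuclei
   are the tracked objects). Nodes are valid inside the Delaunay hull of
   the sample positions; there is no extrapolation.
3. **Height.** z at each valid node by piecewise-linear interpolation over
   the Delaunay triangulation of the samples.
4. **Velocity field.** Each component fitted independently over (x, y) by a
   thin-plate spline (`scipy` RBF with linear polynomial tail): exact on
   linear fields at smoothing 0, robust on scattered data, with a smoothing
   parameter ≥ 0 for noisy data. A FITPACK bivariate-spline backend is
   available (`method="fitpack"`), but FITPACK's scattered-data smoother is
   numerically fragile at smoothing 0, so the thin-plate spline is the
   default.
5. **Planar divergences.** Central differences along grid lines (one-sided
   at the hull boundary) give the 2D divergences in the xy, xz and yz
   planes. The out-of-plane term ∂v_z/∂z is computed along a grid line as
   (Δv_z/Δs)/(Δz/Δs), i.e. the ratio of the vertical-velocity gradient to
   the height slope along that line.
6. **Combination.** Nodal divergence = (D_xy + D_yz + D_xz)/2. Each of the
   three partials ∂v_x/∂x, ∂v_y/∂y, ∂v_z/∂z appears in exactly two planes,
   so half the sum is algebraically the full 3D divergence. An alternative
   intrinsic surface divergence (first-fundamental-form based,
   `mode="intrinsic"`) is provided for sensitivity analysis.
7. **Summary.** Per frame pair: the unweighted arithmetic mean over valid
   nodes (negative = constriction, positive = expansion), the location of
   the most negative node and, when a midline is given, its distance to the
   midline. The per-frame means are also reported in per-frame units
   (mean × frame interval) alongside s⁻¹, because the physically meaningful
   normalization of a published divergence value can be ambiguous and both
   scales are cheap to emit.

## Guarding the out-of-plane term

The ratio (Δv_z/Δs)/(Δz/Δs) is ill-posed wherever the surface is locally
flat along a grid line, and pathological under tracking noise:

- **Flat-surface guard.** If |Δz/Δs| ≤ `slope_eps` (default 1e-3,
  dimensionless slope) the term is set to zero: on a locally flat line the
  out-of-plane term must vanish. A slope threshold (rather than an absolute
  Δz in µm) keeps the guard independent of grid spacing, so the coarse
  pipeline grid and the fine-spacing verification oracle guard the same
  regions of the same surface.
- **Noise-aware guard.** With z tracking noise of sd σ, the interpolated
  height slopes at grid spacing Δx carry noise ≈ √2·σ/(2Δx) — at σ = 1 µm
  and Δx = 5 µm that is ±0.14, typically larger than real tissue slopes.
  Worse, the v_z and z errors share an origin, so the ratio's conditional
  expectation is −1/Δt wherever noise dominates the slope — a large,
  purely artifactual constriction signal (measured: it shifted a true mean
  of −2×10⁻⁵ s⁻¹ to −1.3×10⁻³ s⁻¹). The pipeline therefore estimates σ_z
  from per-track second differences of z (for smooth motion with i.i.d.
  noise, Var(Δ²z) = 6σ²) and raises the guard threshold to
  4·√2·σ_z/(2Δx). The factor 4 (not 3) is deliberate: slope estimates in
  the guard's tail still carry the −1/Δt ratio bias, and at 4σ the leakage
  is negligible. Noiseless data (σ_z ≈ 0) reduce to the plain slope guard.

One consequence is stated plainly: with µm-scale tracking noise at the
default grid spacing, the out-of-plane contribution is effectively
unresolvable and the measured divergence is carried by the in-plane terms.
Resolving curved-surface contributions requires either low noise or a
coarser grid relative to the noise.

## Tunable parameters

| parameter | unit | default | notes |
| --- | --- | --- | --- |
| `nucleus_size` | µm | 5 | sets default grid spacing; spacing capped < 2× |
| `spacing` | µm | `nucleus_size` | explicit override, same cap |
| `smoothing` | — | 0 | thin-plate-spline smoothing; 0 = interpolating. For µm-noise tracks use ≈ 300 (calibrated on synthetic scenes at the default velocity scale) |
| `slope_eps` | — | 1e-3 | flat-surface guard on |dz/ds| |
| `z_noise_sd` | µm | `"auto"` | z tracking noise for the noise-aware guard; `"auto"` estimates from second differences, `None` disables |
| `noise_guard_factor` | — | 4 | guard threshold in units of slope-noise sd |
| `min_duration` | frames | 10 | track filter; the filtering criteria are standard, the numbers are analysis choices |
| `min_displacement` | µm | 5 | net first-to-last displacement filter |
| `d_eps` | µm | 1e-6 | tie tolerance for "neutral" directionality |

Directionality uses 3D point-to-line distances by default (tracks carry z);
an xy-projected mode mirrors 2D figure panels. Distances are to the
infinite line through the midline endpoints (a single tracked reference
cannot constrain more); segment-clamped distance is available. Angles are
reported on the half-rose convention [0°, 180°] with the venous-pole →
arterial-pole orientation; swapping the endpoints maps θ → 180° − θ.

Division planes: the plane is perpendicular to the daughter-separation
axis, so its angle to the midline is 90° minus the axis-to-midline angle,
folded to [0°, 90°]. The class boundary at 45° is assigned to
"perpendicular"; the boundary assignment is a convention, stated in output.
Distance-category bounds are closed above ((50, 150] etc.), with the
innermost band closed at 0. Density bands are xy-projected disks/annuli;
only the unbounded outer band is clipped to the data hull, and excluded
regions (e.g. optically obscured areas) are subtracted from both counts
and areas.

## Synthetic scenes: what they emulate and what they do not

The generator advects cells through prescribed flows (translation,
rotation, isotropic contraction/expansion, midline convergence, a compact
midline sink, and sums of these) on flat, inclined or gently curved
paraboloid surfaces, using explicit Euler with 10 sub-steps per frame and
projection back onto z = f(x, y) after each sub-step (cells stay exactly in
the monolayer, matching the laminar-surface treatment). Tracking noise is
additive i.i.d. Gaussian per coordinate per frame; real trackers have
correlated, anisotropic, occasionally catastrophic errors that this does
not model. Ground-truth (noise-free) positions, division classes and
polygon areas ride along in the outputs, so every downstream stage can be
checked against exact expectations.

The reference scene mirrors a typical dorsal-pericardium acquisition: 150
tracks, 43 frames every 720 s, 5 µm nuclei, 1 µm noise, on a flat surface,
with a composite flow: linear midline convergence at rate k = 2×10⁻⁵ s⁻¹
(the tissue contracts about 2-fold across the ~8.4 h movie) plus a compact
midline sink of amplitude 20k and half-width 50 µm. The sink models the
observed phenomenon that constriction concentrates at the midline where
cells extrude: its velocity vanishes at the support edge, so its divergence
integrates to exactly zero over any region containing the support — the
tissue-mean divergence remains −k — while the midline carries a hotspot of
nodal divergence −21k. The 20-fold contrast is chosen so the hotspot
stands clearly above the nodal noise produced by 1 µm tracking error at the
default acquisition settings; a pure linear convergence has spatially
constant divergence and therefore *no* preferred minimum location, which
would contradict the phenomenon the scene exists to emulate. The
noise-recovery benchmark runs on a flat surface because (see the guard
section) the out-of-plane term is unresolvable at 1 µm noise; curved
geometry is verified separately on noiseless scenes against a
finite-difference oracle at 0.05 µm spacing that uses the identical
measurement convention (same combination rule, same guard).

Passing these benchmarks shows the implementation recovers known
kinematics under the stated noise model at the stated scale. It does not
show robustness to tracker failure modes, segmentation bias, optical
distortion or tissue rotation out of the height-field regime.

## Numerical details and degenerate inputs

- Rigid rotation sampled at finite Δt has apparent divergence −ω²Δt even
  for perfect tracks (the chord underestimates the arc); explicit Euler
  adds +ω²Δt/substeps. Benchmarks use ω = 10⁻⁴ rad/s at 60 s sampling
  (ω²Δt ≈ 6×10⁻¹⁰ s⁻¹), i.e. slow tissue-scale rotation.
- Fewer than 3 non-collinear sample points, or an empty triangulation,
  aborts the frame (hard error in the unit operation; the orchestrator
  logs and skips the frame).
- Nodes whose required derivative has no valid in-line neighbor are
  dropped from the field and the mean; frames with zero valid nodes are
  flagged and skipped.
- Tracks advected off the surface extent are truncated at the last
  in-bounds frame and flagged; tracks shorter than 2 frames are dropped.
- Duplicate (track_id, frame) rows, non-monotonic clocks, and frame
  intervals inconsistent beyond 1% are hard ingestion errors; rows with
  non-numeric coordinates are dropped with a logged count.
- Kruskal–Wallis on all-identical samples is tie-degenerate and returned
  flagged with a NaN p-value rather than raising. The post-hoc after a
  significant Kruskal–Wallis across >2 groups is Dunn's rank z-test with
  tie correction and Bonferroni adjustment (implemented here; labelled in
  the output).
- The half-rose histogram uses left-closed bins on [0°, 180°); an angle of
  exactly 180° is counted in the last bin so totals are conserved.
  Division-distance histograms use right-closed bins (lo, hi], so a
  distance exactly on an interior edge falls in the lower bin.
- All randomness flows through one `numpy` Generator per scene, seeded
  explicitly; the seed is echoed in scene metadata and run summaries, and
  equal seeds give byte-identical outputs.

## Known limitations

- The height-field (Monge patch) representation cannot describe folded or
  vertical tissue; the surface must be single-valued over xy.
- The planar-combination divergence is the measurement convention of the
  original tool family, not the intrinsic surface divergence; on curved
  surfaces the two differ (e.g. midline convergence on a paraboloid flank
  measures −2k rather than −k). The intrinsic mode exists precisely to
  quantify that difference on real data.
- Per-frame grids are rebuilt from that frame's positions; node identity
  is not tracked across frames, so nodal time series are Eulerian, not
  Lagrangian.
- Drift correction is rigid translation from a single reference track; it
  cannot correct rotation or scale drift.
- The unweighted node mean weights the surface by grid coverage of the
  hull, not by triangle area; for strongly non-convex tissues the hull
  overestimates the covered surface.
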