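"""Surface grid, interpolation, planar divergences and the full series."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Point

from tissuekin.divergence import (
    DivergenceParams,
    _masked_derivative,
    build_grid,
    combine_divergence,
    divergence_series,
    interpolate_height,
    interpolate_velocity,
    intrinsic_divergence,
    mean_divergence,
    planar_divergence,
)
from tissuekin.specs import FlowSpec, SceneSpec, SurfaceSpec
from tissuekin.synthetic import analytic_divergence, generate_tracks


def _samples_from_field(points, vfunc):
    """Velocity-sample table at given xy points from a callable field."""
    P = np.atleast_2d(points)
    V = np.array([vfunc(x, y) for x, y in P[:, :2]])
    return pd.DataFrame({
        "x_um": P[:, 0], "y_um": P[:, 1],
        "z_um": P[:, 2] if P.shape[1] > 2 else 0.0,
        "vx_um_s": V[:, 0], "vy_um_s": V[:, 1], "vz_um_s": V[:, 2]})


class TestBuildGrid:
    def test_spacing_bound_and_square_validity(self):
        pts = np.array([[0, 0, 0], [100, 0, 0], [100, 100, 0], [0, 100, 0]], float)
        grid = build_grid(pts, nucleus_size=5.0)
        assert grid.spacing < 10.0
        # all interior nodes of the square hull are valid
        X, Y = grid.meshgrid()
        interior = (X > 1) & (X < 99) & (Y > 1) & (Y < 99)
        assert grid.valid[interior].all()

    def test_spacing_capped_below_twice_nucleus(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 3))
        grid = build_grid(pts, nucleus_size=5.0, spacing=25.0)
        assert grid.spacing < 10.0

    def test_collinear_points_error(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            build_grid(pts, nucleus_size=5.0)

    def test_validity_matches_hull_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-80, 80, size=(150, 2))
        grid = build_grid(pts, nucleus_size=5.0)
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        X, Y = grid.meshgrid()
        for iy in range(0, grid.shape[0], 3):
            for ix in range(0, grid.shape[1], 3):
                p = Point(X[iy, ix], Y[iy, ix])
                # skip points within a hair of the hull boundary, where the
                # two predicates may legitimately disagree in float
                if hull.boundary.distance(p) < 1e-9:
                    continue
                assert grid.valid[iy, ix] == hull.covers(p)


class TestInterpolation:
    def test_height_exact_on_plane(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-50, 50, size=(100, 2))
        z = 2 * xy[:, 0] + 3 * xy[:, 1] + 1
        pts = np.column_stack([xy, z])
        grid = interpolate_height(pts, build_grid(pts, 5.0))
        X, Y = grid.meshgrid()
        expect = 2 * X + 3 * Y + 1
        np.testing.assert_allclose(grid.z[grid.valid], expect[grid.valid], atol=1e-9)

    def test_height_zero_on_flat(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([rng.uniform(-50, 50, (40, 2)), np.zeros(40)])
        grid = interpolate_height(pts, build_grid(pts, 5.0))
        assert np.nanmax(np.abs(grid.z)) < 1e-12

    def test_height_second_order_on_paraboloid(self):
        """Piecewise-linear interpolation error is bounded by C·h² with h
        the data spacing (curvature-controlled constant)."""
        R = 200.0
        g = np.linspace(-50, 50, 21)  # data spacing 5 µm
        X0, Y0 = np.meshgrid(g, g)
        pts = np.column_stack([X0.ravel(), Y0.ravel(),
                               -(X0.ravel()**2 + Y0.ravel()**2) / (2 * R)])
        grid = interpolate_height(pts, build_grid(pts, 5.0, spacing=3.3))
        X, Y = grid.meshgrid()
        expect = -(X**2 + Y**2) / (2 * R)
        err = np.abs(grid.z - expect)[grid.valid].max()
        assert err <= (1.0 / R) * 5.0**2  # C h^2 with generous C

    def test_velocity_constant_and_linear_reproduced(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(-60, 60, (80, 2)), np.zeros(80)])
        grid = interpolate_height(pts, build_grid(pts, 5.0))
        k = 1e-4
        field = interpolate_velocity(
            _samples_from_field(pts, lambda x, y: (0.1, 0.0, 0.0)), grid)
        np.testing.assert_allclose(field.vx[grid.valid], 0.1, atol=1e-9)
        field = interpolate_velocity(
            _samples_from_field(pts, lambda x, y: (-k * x, 0.0, 0.0)), grid)
        X, _ = grid.meshgrid()
        np.testing.assert_allclose(field.vx[grid.valid], -k * X[grid.valid],
                                   atol=1e-6 * k * 60)

    def test_noisy_linear_field_smoothing_reduces_rms(self):
        """With measurement noise, the smoothing spline beats the
        interpolating one against the true linear field."""
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.uniform(-60, 60, (120, 2)), np.zeros(120)])
        grid = interpolate_height(pts, build_grid(pts, 5.0))
        k = 1e-4
        sd = 2e-3
        noisy = _samples_from_field(pts, lambda x, y: (-k * x, 0.0, 0.0))
        noisy["vx_um_s"] += rng.normal(0, sd, len(noisy))
        X, _ = grid.meshgrid()
        truth = -k * X[grid.valid]
        rms = {}
        for s in (0.0, 300.0):
            f = interpolate_velocity(noisy, grid, smoothing=s)
            rms[s] = np.sqrt(np.mean((f.vx[grid.valid] - truth) ** 2))
        assert rms[300.0] < rms[0.0]
        assert rms[300.0] < sd

    def test_too_few_samples_for_fitpack_errors(self):
        pts = np.column_stack([np.random.default_rng(1).uniform(0, 50, (6, 2)),
                               np.zeros(6)])
        grid = interpolate_height(pts, build_grid(pts, 5.0))
        with pytest.raises(ValueError, match="degree"):
            interpolate_velocity(_samples_from_field(pts, lambda x, y: (0, 0, 0)),
                                 grid, method="fitpack", degree=3)


def _contraction_setup(k=1e-4, n=200, seed=9, surface=None):
    surface = surface or SurfaceSpec("flat")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-100, 100, size=(n, 2))
    z = surface.height(xy[:, 0], xy[:, 1])
    pts = np.column_stack([xy, z])
    grid = interpolate_height(pts, build_grid(pts, 5.0))
    samples = _samples_from_field(pts, lambda x, y: (-k * x, -k * y, 0.0))
    field = interpolate_velocity(samples, grid)
    return k, grid, field


class TestPlanarAndCombined:
    def test_planar_xy_contraction(self):
        k, grid, field = _contraction_setup()
        d = planar_divergence(field, grid, "xy")
        interior = grid.valid.copy()
        interior[[0, -1], :] = interior[:, [0, -1]] = False
        np.testing.assert_allclose(d[interior], -2 * k, rtol=5e-3)

    def test_planar_xz_yz_flat_guard(self):
        """On a flat surface the z-terms are guarded off: the xz and yz
        planar divergences reduce to their single in-plane term, -k each."""
        k, grid, field = _contraction_setup()
        interior = grid.valid.copy()
        interior[[0, -1], :] = interior[:, [0, -1]] = False
        np.testing.assert_allclose(planar_divergence(field, grid, "xz")[interior],
                                   -k, rtol=5e-3)
        np.testing.assert_allclose(planar_divergence(field, grid, "yz")[interior],
                                   -k, rtol=5e-3)

    def test_unknown_plane_and_mismatched_grids(self):
        k, grid, field = _contraction_setup()
        with pytest.raises(ValueError):
            planar_divergence(field, grid, "zz")
        with pytest.raises(ValueError):
            combine_divergence(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((4, 3)))

    def test_combined_equals_direct_sum_identity(self):
        """(Dxy + Dyz + Dxz)/2 equals dvx/dx + dvy/dy + dvz/dz computed
        from the same grid derivatives, to rounding."""
        k, grid, field = _contraction_setup(surface=SurfaceSpec(
            "paraboloid_cap", radius=300.0, slope=(0.3, 0.25), extent=150.0))
        d = combine_divergence(planar_divergence(field, grid, "xy"),
                               planar_divergence(field, grid, "yz"),
                               planar_divergence(field, grid, "xz"))
        dvx = _masked_derivative(field.vx, grid.valid, grid.spacing, 1)
        dvy = _masked_derivative(field.vy, grid.valid, grid.spacing, 0)
        dvz_x = _masked_derivative(field.vz, grid.valid, grid.spacing, 1)
        dz_x = _masked_derivative(grid.z, grid.valid, grid.spacing, 1)
        dvz_y = _masked_derivative(field.vz, grid.valid, grid.spacing, 0)
        dz_y = _masked_derivative(grid.z, grid.valid, grid.spacing, 0)
        tx = np.where(np.abs(dz_x) > 1e-3, dvz_x / dz_x, 0.0)
        ty = np.where(np.abs(dz_y) > 1e-3, dvz_y / dz_y, 0.0)
        direct = dvx + dvy + 0.5 * (tx + ty)
        m = np.isfinite(d) & np.isfinite(direct)
        np.testing.assert_allclose(d[m], direct[m], rtol=1e-9)

    def test_mean_divergence_uniform_and_contraction(self):
        assert mean_divergence(np.full((4, 4), 3.0)) == pytest.approx(3.0)
        k, grid, field = _contraction_setup()
        d = combine_divergence(planar_divergence(field, grid, "xy"),
                               planar_divergence(field, grid, "yz"),
                               planar_divergence(field, grid, "xz"))
        assert mean_divergence(d) == pytest.approx(-2 * k, rel=0.01)
        assert np.isnan(mean_divergence(np.full((3, 3), np.nan)))

    def test_intrinsic_mode_flat_contraction(self):
        k, grid, field = _contraction_setup()
        d = intrinsic_divergence(field, grid)
        interior = grid.valid.copy()
        interior[[0, -1], :] = interior[:, [0, -1]] = False
        np.testing.assert_allclose(d[interior], -2 * k, rtol=5e-3)


class TestDivergenceSeries:
    def test_rigid_motions_near_zero(self):
        for flow in (FlowSpec("translation", velocity=(0.05, 0.02, 0.0)),
                     FlowSpec("rotation", omega=1e-4, axis=(0, 0, 1))):
            sc = SceneSpec(flow=flow, n_cells=150, n_frames=4,
                           frame_interval=60.0, noise_sd=0.0, seed=3)
            res = divergence_series(generate_tracks(sc))
            assert np.abs(res.nodes["div_per_s"]).max() < 1e-6

    def test_linearity_of_flows(self):
        """Divergence of a sum of linear flows is the sum of divergences."""
        k1, k2 = 1e-4, 5e-5
        parts = (FlowSpec("isotropic_contraction", rate=k1),
                 FlowSpec("midline_convergence", rate=k2))
        means = []
        for flow in (parts[0], parts[1], FlowSpec("composite", parts=parts)):
            sc = SceneSpec(flow=flow, n_cells=150, n_frames=3,
                           frame_interval=60.0, noise_sd=0.0, seed=5)
            means.append(divergence_series(generate_tracks(sc)).grand_mean)
        assert means[2] == pytest.approx(means[0] + means[1], rel=0.01)

    def test_sign_contract_and_symmetry(self):
        """Constriction scenes negative, expansion positive, symmetric in
        magnitude."""
        k = 1e-4
        out = {}
        for kind in ("isotropic_contraction", "isotropic_expansion"):
            sc = SceneSpec(flow=FlowSpec(kind, rate=k), n_cells=150, n_frames=3,
                           frame_interval=60.0, noise_sd=0.0, seed=6)
            out[kind] = divergence_series(generate_tracks(sc)).grand_mean
        assert out["isotropic_contraction"] < 0 < out["isotropic_expansion"]
        assert abs(out["isotropic_expansion"]) == pytest.approx(
            abs(out["isotropic_contraction"]), rel=0.05)

    def test_grid_refinement_reduces_error_to_floor(self):
        """Halving the grid spacing reduces the RMS error against the
        oracle for a smooth flow, down to the interpolation floor."""
        k = 1e-4
        surf = SurfaceSpec("paraboloid_cap", radius=800.0, slope=(0.35, 0.3),
                           extent=150.0)
        flow = FlowSpec("composite", parts=(
            FlowSpec("midline_convergence", rate=k),
            FlowSpec("midline_sink", rate=k, width=40.0)))
        sc = SceneSpec(flow=flow, surface=surf, n_cells=1200, n_frames=3,
                       frame_interval=60.0, noise_sd=0.0, seed=8)
        ts = generate_tracks(sc)
        errs = []
        for spacing in (9.0, 4.5, 2.25):
            res = divergence_series(ts, DivergenceParams(spacing=spacing))
            nod = res.nodes[res.nodes.frame == 0]
            P = nod[["x_um", "y_um"]].to_numpy()
            m = (np.abs(P[:, 0]) < 150 - 2 * spacing) & (np.abs(P[:, 1]) < 150 - 2 * spacing)
            oracle = analytic_divergence(flow, surf, P[m])
            errs.append(np.sqrt(np.mean((nod["div_per_s"].to_numpy()[m] - oracle) ** 2))
                        / np.sqrt(np.mean(oracle**2)))
        assert errs[1] < errs[0]
        assert errs[2] < errs[1] * 1.3  # at/near the discretization floor
        assert errs[1] < 0.10

    def test_midline_minimum_location_noiseless(self, midline_y):
        """With a constriction hotspot on the midline, the most negative
        node sits at the midline in every noiseless frame."""
        k = 2e-5
        flow = FlowSpec("composite", parts=(
            FlowSpec("midline_convergence", rate=k),
            FlowSpec("midline_sink", rate=20 * k, width=50.0)))
        sc = SceneSpec(flow=flow, n_cells=150, n_frames=6, frame_interval=720.0,
                       noise_sd=0.0, seed=10)
        res = divergence_series(generate_tracks(sc), DivergenceParams(),
                                midline=midline_y)
        fm = res.frame_means
        assert (fm["min_dist_to_midline_um"] <= 2 * fm["grid_spacing_um"]).all()
        assert (fm["mean_div_per_s"] < 0).all()

    def test_per_frame_units_column(self, midline_y):
        sc = SceneSpec(flow=FlowSpec("isotropic_contraction", rate=1e-4),
                       n_cells=80, n_frames=3, frame_interval=300.0,
                       noise_sd=0.0, seed=2)
        res = divergence_series(generate_tracks(sc))
        fm = res.frame_means
        np.testing.assert_allclose(fm["mean_div_per_frame"],
                                   fm["mean_div_per_s"] * 300.0)
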