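"""Monodomain solver: tensors, propagation, CV and stability properties."""
import numpy as np
import pytest

from virtuheart import config, fusion, geometry, ionic, monodomain as md
from virtuheart.fusion import TissueLabelMap
from virtuheart.geometry import FiberField, build_grid
from virtuheart.monodomain import (MonodomainConfig, Stimulus, prepare,
                                   simulate)


def strip_mesh(cfg, ny=3, ncols=40, h_mm=1.0, fiber=(1.0, 0.0, 0.0),
               labels=None):
    if labels is None:
        labels = np.ones((ny, ncols), dtype=np.int8)
    grid = build_grid(TissueLabelMap(labels, (h_mm, h_mm)), h_mm * 1000.0)
    m = grid.n_elements
    f = np.tile(np.asarray(fiber, dtype=float), (m, 1))
    fib = FiberField(f, np.zeros(m), np.tile([0.0, 1.0, 0.0], (m, 1)))
    return grid, prepare(grid, fib, cfg)


class TestConductivity:
    def test_fiber_along_x_gives_diagonal_tensor(self):
        cfg = MonodomainConfig()
        grid, mesh = strip_mesh(cfg)
        fib = FiberField(np.tile([1.0, 0.0, 0.0], (grid.n_elements, 1)),
                         np.zeros(grid.n_elements),
                         np.tile([0.0, 1.0, 0.0], (grid.n_elements, 1)))
        tens = md.assemble_conductivity(grid, fib, cfg)
        np.testing.assert_allclose(tens[:, 0], cfg.d_l)
        np.testing.assert_allclose(tens[:, 1], cfg.d_t)
        np.testing.assert_allclose(tens[:, 2], 0.0)

    def test_isotropic_independent_of_fiber(self, rng):
        sig = config.SIGMA_L_S_M
        cfg = MonodomainConfig(sigma_l=sig, sigma_t=sig)
        grid, _ = strip_mesh(cfg)
        m = grid.n_elements
        ang = rng.uniform(0, 2 * np.pi, m)
        f = np.stack([np.cos(ang), np.sin(ang), np.zeros(m)], axis=1)
        fib = FiberField(f, np.rad2deg(ang), np.roll(f, 1, axis=1))
        tens = md.assemble_conductivity(grid, fib, cfg)
        np.testing.assert_allclose(tens[:, 0], cfg.d_l, rtol=1e-12)
        np.testing.assert_allclose(tens[:, 2], 0.0, atol=1e-15)

    def test_nonunit_fiber_rejected(self):
        cfg = MonodomainConfig()
        grid, _ = strip_mesh(cfg)
        m = grid.n_elements
        fib = FiberField(np.tile([0.9, 0.0, 0.0], (m, 1)), np.zeros(m),
                         np.tile([0.0, 1.0, 0.0], (m, 1)))
        with pytest.raises(ValueError):
            md.assemble_conductivity(grid, fib, cfg)


class TestPropagation:
    def test_quiescence_without_stimulus(self):
        cfg = md.desk_config()
        _, mesh = strip_mesh(cfg, ncols=20)
        rec = simulate(mesh, [], cfg, duration_ms=1000.0)
        assert not rec.activated.any()
        # resting uniform state stays stationary
        assert np.abs(rec.final_state[0] - rec.final_state[0][0]).max() < 0.01

    def test_planar_activation_linear_in_distance(self):
        cfg = MonodomainConfig(dt_ms=0.02)
        _, mesh = strip_mesh(cfg, h_mm=0.35, ncols=100)
        left = np.nonzero(mesh.coords[:, 0] <= 0.7)[0]
        rec = simulate(mesh, [Stimulus(left, 5.0)], cfg, duration_ms=80.0)
        t = rec.first_activation()
        # exclude the stimulus-acceleration and boundary regions
        sel = np.isfinite(t) & (mesh.coords[:, 0] > 5.0) & \
            (mesh.coords[:, 0] < 30.0)
        x = mesh.coords[sel, 0]
        r = np.corrcoef(x, t[sel])[0, 1]
        assert r ** 2 > 0.999

    def test_point_stimulus_isotropic_isochrones(self):
        sig = config.SIGMA_L_S_M
        cfg = MonodomainConfig(sigma_l=sig, sigma_t=sig, dt_ms=0.02)
        labels = np.ones((30, 30), dtype=np.int8)
        grid, mesh = strip_mesh(cfg, ny=30, ncols=30, h_mm=0.5, labels=labels)
        center = mesh.coords.mean(axis=0)
        src = mesh.nodes_within(center, 0.8)
        rec = simulate(mesh, [Stimulus(src, 5.0)], cfg, duration_ms=40.0)
        t = rec.first_activation()
        sel = np.isfinite(t) & (t > 12.0) & (t < 18.0)
        d = np.linalg.norm(mesh.coords[sel] - center, axis=1)
        dx = np.abs(mesh.coords[sel, 0] - center[0])
        dy = np.abs(mesh.coords[sel, 1] - center[1])
        # wavefront radius comparable along both axes
        rx = dx[dx > dy].mean() if (dx > dy).any() else d.mean()
        ry = dy[dy >= dx].mean() if (dy >= dx).any() else d.mean()
        assert rx / ry == pytest.approx(1.0, abs=0.2)

    def test_dense_scar_blocks_all_flux(self):
        """Tissue behind a transmural dense wall never activates."""
        cfg = md.desk_config()
        labels = np.ones((3, 40), dtype=np.int8)
        labels[:, 18:22] = 3
        _, mesh = strip_mesh(cfg, labels=labels)
        left = np.nonzero(mesh.coords[:, 0] <= 1.0)[0]
        rec = simulate(mesh, [Stimulus(left, 5.0)], cfg, duration_ms=500.0,
                       stop_quiescent=True)
        behind = mesh.coords[:, 0] > 22.0
        assert rec.activated[~behind & (mesh.coords[:, 0] < 17.0)].any()
        assert not rec.activated[behind].any()
        # resting tissue adjacent to scar stays at rest (no leak)
        assert rec.final_state[0][behind].max() < -80.0

    def test_axis_permutation_invariance(self):
        cfg = md.desk_config()
        _, mesh_x = strip_mesh(cfg, ny=3, ncols=30, fiber=(1.0, 0.0, 0.0))
        left = np.nonzero(mesh_x.coords[:, 0] <= 1.0)[0]
        rec_x = simulate(mesh_x, [Stimulus(left, 5.0)], cfg, duration_ms=300.0)
        labels_t = np.ones((30, 3), dtype=np.int8)
        _, mesh_y = strip_mesh(cfg, ny=30, ncols=3, fiber=(0.0, 1.0, 0.0),
                               labels=labels_t)
        bottom = np.nonzero(mesh_y.coords[:, 1] <= 1.0)[0]
        rec_y = simulate(mesh_y, [Stimulus(bottom, 5.0)], cfg,
                         duration_ms=300.0)
        tx = np.sort(rec_x.first_activation())
        ty = np.sort(rec_y.first_activation())
        np.testing.assert_allclose(tx, ty, atol=1e-9)

    def test_instability_aborts_with_diagnostics(self):
        cfg = MonodomainConfig(dt_ms=0.02)
        _, mesh = strip_mesh(cfg, ncols=10)
        huge = Stimulus(np.arange(mesh.n_nodes), 5.0, duration_ms=50.0,
                        amplitude=-500.0)
        with pytest.raises(md.SimulationError, match="instability"):
            simulate(mesh, [huge], cfg, duration_ms=100.0)

    def test_cfl_guard(self):
        cfg = MonodomainConfig(dt_ms=0.05)
        with pytest.raises(md.SimulationError, match="unstable"):
            strip = strip_mesh(cfg, h_mm=0.1, ncols=20)
            simulate(strip[1], [], cfg, duration_ms=1.0)


class TestConductionVelocity:
    def test_cv_requires_enough_points(self):
        cfg = md.desk_config()
        _, mesh = strip_mesh(cfg, ncols=20)
        rec = simulate(mesh, [], cfg, duration_ms=10.0)
        with pytest.raises(ValueError):
            md.measure_cv(rec)

    def test_calibrated_cv_within_5pct_across_mesh_window(self):
        """Planar CV stays within 5% of 0.6 m/s over 300-400 um edges."""
        cfg = MonodomainConfig(dt_ms=0.02)
        for dx in (300.0, 400.0):
            cv = md._strip_cv(cfg, dx)
            assert cv == pytest.approx(0.6, rel=0.05)

    def test_cv_anisotropy_matches_sqrt_sigma_ratio(self):
        """CV_l / CV_t -> sqrt(sigma_l/sigma_t) on a fine grid."""
        cfg = MonodomainConfig(dt_ms=0.008)
        cvl = md._strip_cv(cfg, 75.0, length_mm=12.0)
        cvt = md._strip_cv(cfg, 75.0, length_mm=12.0, direction="t")
        ratio = cvl / cvt
        assert ratio == pytest.approx(np.sqrt(config.ANISOTROPY_SIGMA_RATIO),
                                      rel=0.05)


class TestTissueCellConsistency:
    def test_single_node_matches_reference_cell(self):
        """The tabulated tissue kernel reproduces the reference single-cell
        integrator on an isolated node through a paced beat."""
        cfg = MonodomainConfig(dt_ms=0.02)
        _, mesh = strip_mesh(cfg, ny=1, ncols=2, h_mm=1.0)
        stim = Stimulus(np.arange(mesh.n_nodes), 10.0, 1.0, -52.0)
        rec = simulate(mesh, [stim], cfg, duration_ms=420.0)
        v_tissue = rec.final_state[0][0]

        p = ionic.make_params("normal")
        s = ionic.initial_state()
        nsteps = int(420.0 / 0.02)
        for k in range(nsteps):
            t = k * 0.02
            i_stim = -52.0 if 10.0 <= t < 11.0 else 0.0
            ionic.ionic_step(s.y, p.to_vector(), 0, 0.02, i_stim)
        assert v_tissue == pytest.approx(s.y[0], abs=1.0)

    def test_wavelength_longer_in_remodeled_cable(self):
        """Remodeled tissue at equal conductivity has a longer wavelength
        (CV x APD) than normal tissue: the APD effect."""
        cfg = md.desk_config()

        def cable(variant):
            labels = np.full((3, 40), 1 if variant == "normal" else 2,
                             dtype=np.int8)
            _, mesh = strip_mesh(cfg, labels=labels)
            left = np.nonzero(mesh.coords[:, 0] <= 1.0)[0]
            rec = simulate(mesh, [Stimulus(left, 5.0)], cfg, duration_ms=600.0)
            cv = md.measure_cv(rec)
            apd = ionic.apd90(ionic.make_params(variant), 1000.0, 20)
            return cv * apd

        assert cable("remodeled") > cable("normal")
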