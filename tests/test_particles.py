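"""Droplet dynamics, collision geometry, seeding, filtration efficiency."""

import numpy as np
import pytest

import weavefilter as wf
from weavefilter.particles import ParticleSpec, Trajectory

from conftest import make_synthetic_field


def make_traj(outcome, weight):
    return Trajectory(particle=ParticleSpec(1.0), start=np.zeros(3),
                      v_z_initial=weight, outcome=outcome, end=np.zeros(3),
                      n_steps=1)


class TestTimescalesAndStokes:
    def test_drag_timescale_value(self):
        """t_I = rho d^2 C/(18 mu): 6.93 us for a 1.5 um water droplet."""
        t = wf.drag_timescale(ParticleSpec(1.5))
        assert t == pytest.approx(6.93e-6, rel=1e-3)

    def test_drag_timescale_quadratic_in_diameter(self):
        assert wf.drag_timescale(ParticleSpec(2.0)) == pytest.approx(
            4 * wf.drag_timescale(ParticleSpec(1.0)))

    def test_stokes_prefactor(self):
        assert wf.stokes_prefactor() == pytest.approx(3.08e6, rel=0.002)

    def test_stokes_number_examples(self):
        assert wf.stokes_number(1e-6, 1e-5, 0.0) == 0.0
        # 10 um droplet, 10 um obstacle, 2.7 cm/s
        st = wf.stokes_number(10e-6, 10e-6, 0.027)
        assert st == pytest.approx(0.832, rel=0.005)

    def test_mass(self):
        spec = ParticleSpec(2.0)
        assert spec.mass_kg == pytest.approx(np.pi / 6 * 8e-18 * 998)


class TestCollision:
    def test_center_inside_solid_always_collides(self, small_weave):
        idx = np.argwhere(small_weave.occupancy == 1)[0].astype(float)
        assert wf.detect_collision(small_weave, idx, 0.1)

    def test_far_from_solid_never_collides(self):
        occ = np.zeros((24, 24, 24), np.uint8)
        occ[0, 0, 0] = 1
        g = wf.VoxelGrid(occ, 1.0)
        assert not wf.detect_collision(g, (12.0, 12.0, 12.0), 1.0)

    def test_matches_exact_point_to_cube_oracle(self):
        """Random sparse geometries and probe spheres: the collision flag
        equals a brute-force exact distance to every solid cube (with
        periodic x/y images)."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            occ = (rng.random((8, 8, 8)) < 0.1).astype(np.uint8)
            grid = wf.VoxelGrid(occ, 1.0)
            p = rng.uniform([0, 0, 0.5], [7.9, 7.9, 7.4])
            d_p = rng.uniform(0.2, 4.0)
            got = wf.detect_collision(grid, p, d_p)
            best = np.inf
            inside = occ[int(round(p[0])) % 8, int(round(p[1])) % 8,
                         int(round(p[2]))] == 1
            for (i, j, k) in np.argwhere(occ):
                for oi in (-8, 0, 8):
                    for oj in (-8, 0, 8):
                        c = np.array([i + oi, j + oj, k], float)
                        dd = np.maximum(np.abs(p - c) - 0.5, 0.0)
                        best = min(best, float(np.linalg.norm(dd)))
            want = True if inside else best < d_p / 2
            assert got == want

    def test_grazing_tolerance(self):
        occ = np.zeros((10, 10, 10), np.uint8)
        occ[5, 5, 5] = 1
        g = wf.VoxelGrid(occ, 2.0)   # pitch 2 um
        # surface at x = 4.5 voxels; particle radius 1 voxel = 2 um
        assert wf.detect_collision(g, (3.6, 5.0, 5.0), 4.0)
        assert not wf.detect_collision(g, (3.4, 5.0, 5.0), 4.0)


class TestIntegrator:
    def test_uniform_field_straight_penetration(self, uniform_plug_field):
        fld = wf.rescale_flow(uniform_plug_field, 0.027)
        tr = wf.integrate_trajectory(fld, ParticleSpec(2.0), (8.0, 8.0, 2.0),
                                     "inertial")
        assert tr.outcome == "penetrated"
        assert np.allclose(tr.end[:2], (8.0, 8.0), atol=1e-9)

    def test_velocity_relaxes_exponentially(self, uniform_plug_field):
        """With constant u and v0 != u the integrator reproduces the exact
        solution v(t) = u + (v0-u) e^(-t/t_I) to 1e-6 relative."""
        fld = wf.rescale_flow(uniform_plug_field, 0.027)
        spec = ParticleSpec(10.0)
        t_i = wf.drag_timescale(spec)
        conv = fld.velocity_scale_m_per_s / (fld.grid.voxel_pitch * 1e-6)
        uz_vox = fld.velocity[0, 0, 0, 2] * conv
        tr = wf.integrate_trajectory(fld, spec, (8.0, 8.0, 2.0), "inertial",
                                     v0=np.zeros(3), record=3000)
        t, vz = tr.path[:, 0], tr.path[:, 6]
        analytic = uz_vox * (1.0 - np.exp(-t / t_i))
        assert np.max(np.abs(vz - analytic)) / uz_vox < 1e-6

    def test_zero_inertia_limit_converges_to_tracer(self, pore_plate_field):
        """As t_I -> 0 the inertial trajectory collapses onto the tracer
        path through a curved pore flow."""
        fld = wf.rescale_flow(pore_plate_field, 0.027)
        start = (17.5, 16.5, 2.0)   # off-axis: curved approach into pore
        step = 0.05                 # refine both modes identically
        tracer = wf.integrate_trajectory(fld, ParticleSpec(0.05), start,
                                         "tracer", step_vox=step)
        assert tracer.outcome == "penetrated"
        deviations = []
        for d in (2.0, 1.0, 0.2):
            inert = wf.integrate_trajectory(fld, ParticleSpec(d), start,
                                            "inertial", step_vox=step)
            assert inert.outcome == "penetrated"
            deviations.append(np.linalg.norm(inert.end - tracer.end))
        assert deviations[2] < deviations[1] < deviations[0]
        assert deviations[2] < 0.1

    def test_requires_physical_scale(self, pore_plate_field):
        with pytest.raises(ValueError, match="velocity scale"):
            wf.integrate_trajectory(pore_plate_field, ParticleSpec(1.0),
                                    (16.0, 16.0, 2.0))

    def test_start_in_contact_rejected(self, pore_plate_field):
        fld = wf.rescale_flow(pore_plate_field, 0.027)
        with pytest.raises(ValueError, match="contact"):
            wf.integrate_trajectory(fld, ParticleSpec(1.0),
                                    (2.0, 2.0, 20.0))


class TestSeeding:
    def test_single_seed_at_center(self, small_weave):
        pts = wf.seed_particles(small_weave, 1)
        nx, ny, _ = small_weave.shape
        assert pts.shape == (1, 3)
        assert pts[0, 0] == pytest.approx(nx / 2)
        assert pts[0, 1] == pytest.approx(ny / 2)

    def test_grid_layout_and_containment(self, small_weave):
        pts = wf.seed_particles(small_weave, 1600)
        nx, ny, _ = small_weave.shape
        assert pts.shape == (1600, 3)
        assert np.unique(pts[:, 0]).size == 40
        spacing = np.diff(np.unique(pts[:, 0]))
        assert np.allclose(spacing, (nx / 2.0) / 40)
        assert pts[:, 0].min() >= nx / 4 and pts[:, 0].max() <= 3 * nx / 4
        assert pts[:, 1].min() >= ny / 4 and pts[:, 1].max() <= 3 * ny / 4

    def test_non_square_rejected(self, small_weave):
        with pytest.raises(ValueError, match="perfect square"):
            wf.seed_particles(small_weave, 1500)


class TestEfficiency:
    def test_all_collided_is_one(self):
        trajs = [make_traj("collided", w) for w in (1.0, 2.0)]
        assert wf.filtration_efficiency(trajs) == 1.0

    def test_none_collided_is_zero(self):
        trajs = [make_traj("penetrated", w) for w in (1.0, 2.0)]
        assert wf.filtration_efficiency(trajs) == 0.0

    def test_hand_weighted_example(self):
        trajs = ([make_traj("collided", w) for w in (1.0, 3.0)]
                 + [make_traj("penetrated", w) for w in (2.0, 2.0)])
        assert wf.filtration_efficiency(trajs) == pytest.approx(0.5)

    def test_invariant_under_weight_rescaling(self):
        trajs = ([make_traj("collided", w) for w in (1.0, 3.0)]
                 + [make_traj("penetrated", w) for w in (2.0, 5.0)])
        scaled = ([make_traj("collided", 10 * w) for w in (1.0, 3.0)]
                  + [make_traj("penetrated", 10 * w) for w in (2.0, 5.0)])
        assert wf.filtration_efficiency(trajs) == pytest.approx(
            wf.filtration_efficiency(scaled))

    def test_unresolved_excluded_with_warning(self, caplog):
        trajs = [make_traj("collided", 1.0), make_traj("penetrated", 1.0),
                 make_traj("unresolved", 5.0)]
        with caplog.at_level("WARNING"):
            eff = wf.filtration_efficiency(trajs)
        assert eff == pytest.approx(0.5)
        assert "unresolved" in caplog.text

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            wf.filtration_efficiency([make_traj("unresolved", 1.0)])


class TestFiltrationCurve:
    def test_open_channel_zero_efficiency(self, uniform_plug_field):
        res = wf.run_filtration_curve(uniform_plug_field, [1.0, 5.0],
                                      modes=("inertial", "tracer"),
                                      n_samp=16)
        for mode in ("inertial", "tracer"):
            assert np.all(res.efficiency[mode] == 0.0)

    def test_full_blockage_unit_efficiency(self):
        """Uniform approach flow into an impenetrable slab captures every
        sampled trajectory."""
        shape = (16, 16, 60)
        occ = np.zeros(shape, np.uint8)
        occ[:, :, 30:36] = 1
        u = np.zeros(shape + (3,))
        u[..., 2] = 1e-5
        fld = make_synthetic_field(occ, u, voxel_pitch=2.0)
        res = wf.run_filtration_curve(fld, [2.0], modes=("inertial",
                                                         "tracer"),
                                      n_samp=16)
        assert np.all(res.efficiency["inertial"] == 1.0)
        assert np.all(res.efficiency["tracer"] == 1.0)

    def test_weave_curve_monotone_and_bounded(self, weave_curve):
        res = weave_curve
        for mode in ("inertial", "tracer"):
            eff = res.efficiency[mode]
            assert np.all((eff >= 0.0) & (eff <= 1.0))
            # interception grows with size; allow sampling noise
            assert np.all(np.diff(eff) > -0.05)
            assert eff[-1] > eff[0]
            for c in res.counts[mode]:
                assert sum(c) == 400
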