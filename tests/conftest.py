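"""Shared fixtures.

Lattice-Boltzmann steady states are expensive, so every converged field is
session-scoped and reused across test modules.  All simulated geometries
here are deliberately coarse/small; they keep the full pipeline physics
(Stokes flow, interception, inertia) at desk scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import weavefilter as wf
from weavefilter.lbm import LBMParams


def make_synthetic_field(occupancy: np.ndarray, velocity: np.ndarray,
                         voxel_pitch: float = 1.0,
                         fabric_z_range=None) -> wf.FlowField:
    """Wrap hand-built velocity data in a FlowField (synthetic, not solved)."""
    grid = wf.VoxelGrid(occupancy.astype(np.uint8), voxel_pitch,
                        fabric_z_range)
    v = velocity.copy()
    v[occupancy.astype(bool)] = 0.0
    return wf.FlowField(velocity=v, density=np.ones(occupancy.shape),
                        grid=grid, params=LBMParams(), converged=True,
                        steps_run=0)


@pytest.fixture(scope="session")
def small_weave_spec() -> wf.FabricSpec:
    """Coarse-pitch plain weave: 2x2 cells of a 120 um lattice at 5 um voxels.

    Scaled-down study geometry: pores stay several voxels wide so both
    interception and flow channeling are resolved.
    """
    return wf.FabricSpec(lattice_constant_x=120.0, lattice_constant_y=120.0,
                         yarn_width=80.0, yarn_thickness=30.0,
                         fabric_thickness=60.0, voxel_pitch=5.0,
                         n_stray_fibers_per_pore=1,
                         target_solid_fraction=0.55, rng_seed=1,
                         air_pad_um=30.0)


@pytest.fixture(scope="session")
def small_weave(small_weave_spec) -> wf.VoxelGrid:
    return wf.generate_plain_weave(small_weave_spec)


@pytest.fixture(scope="session")
def weave_field(small_weave) -> wf.FlowField:
    fld = wf.run_lbm(small_weave, LBMParams(convergence_tol=1e-6,
                                            max_steps=30_000))
    assert fld.converged
    return fld


@pytest.fixture(scope="session")
def weave_field_physical(weave_field) -> wf.FlowField:
    """Weave flow rescaled to the moderate-exertion face velocity."""
    return wf.rescale_flow(weave_field, 0.027)


@pytest.fixture(scope="session")
def weave_curve(weave_field_physical):
    """Filtration efficiency vs diameter on the scaled-down weave."""
    return wf.run_filtration_curve(weave_field_physical,
                                   [2.0, 5.0, 10.0, 20.0], n_samp=400)


@pytest.fixture(scope="session")
def poiseuille_field() -> wf.FlowField:
    """Plane-Poiseuille channel, width H = 20 fluid nodes, flow along z."""
    g = wf.generate_fixture("parallel_plates", shape=(24, 4, 41),
                            channel_width=20)
    fld = wf.run_lbm(g, LBMParams(convergence_tol=1e-7, max_steps=60_000))
    assert fld.converged
    return fld


@pytest.fixture(scope="session")
def pore_plate_field() -> wf.FlowField:
    """Plate with one 12-voxel circular through-pore (curved-flow fixture)."""
    g = wf.generate_fixture("circular_pore_plate", shape=(32, 32, 40),
                            z_lo=14, z_hi=26, pore_diameter=12)
    fld = wf.run_lbm(g, LBMParams(convergence_tol=1e-7, max_steps=60_000))
    assert fld.converged
    return fld


@pytest.fixture(scope="session")
def pore_plate_field_double_dp(pore_plate_field) -> wf.FlowField:
    """Same pore plate driven at twice the density contrast."""
    g = pore_plate_field.grid
    fld = wf.run_lbm(g, LBMParams(inlet_density=1 + 2e-5,
                                  outlet_density=1 - 2e-5,
                                  convergence_tol=1e-7, max_steps=60_000))
    assert fld.converged
    return fld


@pytest.fixture(scope="session")
def rotation_field() -> wf.FlowField:
    """Solid-body rotation about the box center: analytic curvature oracle."""
    nx = ny = 41
    nz = 5
    occ = np.zeros((nx, ny, nz), np.uint8)
    u = np.zeros((nx, ny, nz, 3))
    omega = 1e-3
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    u[..., 0] = (-omega * (y - 20.0))[:, :, None]
    u[..., 1] = (omega * (x - 20.0))[:, :, None]
    return make_synthetic_field(occ, u)


@pytest.fixture(scope="session")
def uniform_plug_field() -> wf.FlowField:
    """Uniform +z plug flow in an empty box (open-channel fixture)."""
    shape = (16, 16, 60)
    u = np.zeros(shape + (3,))
    u[..., 2] = 1e-5
    return make_synthetic_field(np.zeros(shape), u, voxel_pitch=2.0,
                                fabric_z_range=(30, 31))
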