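"""Single-relaxation-time D3Q19 lattice-Boltzmann solver for Stokes air flow.

The solver computes the steady, low-Mach, pressure-driven flow of air
through a binary voxel geometry:

- BGK collision on the 19-velocity cubic lattice, weights {1/3, 1/18, 1/36},
  speed of sound c_s^2 = 1/3 in lattice units; kinematic viscosity
  nu_LB = c_s^2 (1/omega - 1/2), so the default omega = 1 gives nu_LB = 1/6.
- Full-way on-site bounce-back at solid (fiber) voxels: a solid node swaps
  each population with its opposite instead of colliding, which places the
  effective no-slip wall half a voxel beyond the last fluid node.
- Periodic boundaries along x and y (the fabric plane).
- Pressure (density) Dirichlet boundaries on the first and last z-slices:
  after streaming, boundary-slice populations are set to equilibrium at the
  prescribed density with the velocity copied from the adjacent interior
  slice.  The default contrast 1 +/- 1e-5 keeps the flow deep in the Stokes
  regime (Re << 1) so the flow pattern is independent of the driving.

The driving pressure difference in lattice units is c_s^2 * (rho_in -
rho_out) = (1/3) * 2e-5 for the defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .grid import VoxelGrid

logger = logging.getLogger(__name__)

CS2 = 1.0 / 3.0

# D3Q19 velocity set: rest, 6 faces, 12 edges.
C = np.array([
    [0, 0, 0],
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
    [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
    [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
], dtype=np.int64)
W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12, dtype=np.float64)
OPP = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9,
                12, 11, 14, 13, 16, 15, 18, 17], dtype=np.int64)


def viscosity_lb(omega: float) -> float:
    """Kinematic viscosity in lattice units for relaxation rate omega."""
    return CS2 * (1.0 / omega - 0.5)


@dataclass
class LBMParams:
    """Solver configuration (lattice units throughout)."""

    omega: float = 1.0
    inlet_density: float = 1.0 + 1e-5
    outlet_density: float = 1.0 - 1e-5
    convergence_tol: float = 1e-7
    check_interval: int = 100
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if not (0.0 < self.omega < 2.0):
            raise ValueError("omega must lie in (0, 2)")
        if self.inlet_density <= self.outlet_density:
            raise ValueError("inlet_density must exceed outlet_density")
        if self.convergence_tol <= 0 or self.check_interval < 1:
            raise ValueError("invalid convergence controls")

    @property
    def nu_lb(self) -> float:
        return viscosity_lb(self.omega)

    @property
    def delta_p_lb(self) -> float:
        """Driving pressure difference c_s^2 (rho_in - rho_out)."""
        return CS2 * (self.inlet_density - self.outlet_density)


@dataclass
class FlowField:
    """Steady-state velocity and density on the lattice (lattice units).

    ``velocity_scale_m_per_s`` records the physical speed one lattice unit
    of velocity corresponds to; it is None until the field is rescaled to a
    target face velocity (see :func:`weavefilter.flow_analysis.rescale_flow`).
    """

    velocity: np.ndarray            # (nx, ny, nz, 3), zero on solid nodes
    density: np.ndarray             # (nx, ny, nz), 1 on solid nodes
    grid: VoxelGrid
    params: LBMParams
    converged: bool
    steps_run: int
    mean_uz_history: list = field(default_factory=list)
    velocity_scale_m_per_s: float | None = None

    @property
    def uz(self) -> np.ndarray:
        return self.velocity[..., 2]

    def mean_uz(self) -> float:
        """Mean u_z over all nodes (solid nodes count as zero flow)."""
        return float(self.velocity[..., 2].mean())


def equilibrium(rho, u):
    """Second-order D3Q19 equilibrium populations.

    ``rho`` scalar or array; ``u`` array with trailing dimension 3.  Returns
    populations with a leading length-19 axis.  At rest the populations are
    the lattice weights times rho, and the first two moments satisfy
    sum_i f_i = rho and sum_i f_i c_i = rho u.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    cu = np.tensordot(C, u, axes=([1], [u.ndim - 1]))          # (19, ...)
    u2 = np.sum(u * u, axis=-1)
    w = W.reshape((19,) + (1,) * cu[0].ndim)
    return w * rho * (1.0 + 3.0 * cu + 4.5 * cu ** 2 - 1.5 * u2)


@njit(cache=True)
def _step(f, fnew, solid, c, w, opp, omega):
    """One fused collide-and-push-stream update over the whole lattice."""
    nx, ny, nz = solid.shape
    post = np.empty(19)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    for i in range(19):
                        post[i] = f[opp[i], x, y, z]
                else:
                    rho = 0.0
                    ux = 0.0
                    uy = 0.0
                    uz = 0.0
                    for i in range(19):
                        fi = f[i, x, y, z]
                        rho += fi
                        ux += fi * c[i, 0]
                        uy += fi * c[i, 1]
                        uz += fi * c[i, 2]
                    ux /= rho
                    uy /= rho
                    uz /= rho
                    usq = ux * ux + uy * uy + uz * uz
                    for i in range(19):
                        cu = (c[i, 0] * ux + c[i, 1] * uy + c[i, 2] * uz)
                        feq = w[i] * rho * (1.0 + 3.0 * cu
                                            + 4.5 * cu * cu - 1.5 * usq)
                        post[i] = f[i, x, y, z] + omega * (feq - f[i, x, y, z])
                for i in range(19):
                    xn = x + c[i, 0]
                    if xn < 0:
                        xn += nx
                    elif xn >= nx:
                        xn -= nx
                    yn = y + c[i, 1]
                    if yn < 0:
                        yn += ny
                    elif yn >= ny:
                        yn -= ny
                    zn = z + c[i, 2]
                    if 0 <= zn < nz:
                        fnew[i, xn, yn, zn] = post[i]


@njit(cache=True)
def _apply_density_bc(f, solid, c, w, rho_in, rho_out):
    """Equilibrium density boundaries on the first/last z-slices.

    Velocity is copied from the adjacent interior node (zero if that node
    is solid), then all 19 populations are replaced by the equilibrium at
    the prescribed boundary density.
    """
    nx, ny, nz = solid.shape
    for x in range(nx):
        for y in range(ny):
            for b in range(2):
                if b == 0:
                    z, zin, rho_b = 0, 1, rho_in
                else:
                    z, zin, rho_b = nz - 1, nz - 2, rho_out
                if solid[x, y, z]:
                    continue
                ux = 0.0
                uy = 0.0
                uz = 0.0
                if not solid[x, y, zin]:
                    rho = 0.0
                    for i in range(19):
                        fi = f[i, x, y, zin]
                        rho += fi
                        ux += fi * c[i, 0]
                        uy += fi * c[i, 1]
                        uz += fi * c[i, 2]
                    ux /= rho
                    uy /= rho
                    uz /= rho
                usq = ux * ux + uy * uy + uz * uz
                for i in range(19):
                    cu = c[i, 0] * ux + c[i, 1] * uy + c[i, 2] * uz
                    f[i, x, y, z] = w[i] * rho_b * (1.0 + 3.0 * cu
                                                    + 4.5 * cu * cu
                                                    - 1.5 * usq)


@njit(cache=True)
def _moments(f, solid, c):
    """Density and velocity fields from populations (solid: u=0, rho=1)."""
    nx, ny, nz = solid.shape
    rho_out = np.ones((nx, ny, nz))
    u_out = np.zeros((nx, ny, nz, 3))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    continue
                rho = 0.0
                ux = 0.0
                uy = 0.0
                uz = 0.0
                for i in range(19):
                    fi = f[i, x, y, z]
                    rho += fi
                    ux += fi * c[i, 0]
                    uy += fi * c[i, 1]
                    uz += fi * c[i, 2]
                rho_out[x, y, z] = rho
                u_out[x, y, z, 0] = ux / rho
                u_out[x, y, z, 1] = uy / rho
                u_out[x, y, z, 2] = uz / rho
    return rho_out, u_out


@njit(cache=True)
def _mean_uz(f, solid, c):
    nx, ny, nz = solid.shape
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    continue
                rho = 0.0
                mz = 0.0
                for i in range(19):
                    fi = f[i, x, y, z]
                    rho += fi
                    mz += fi * c[i, 2]
                total += mz / rho
    return total / (nx * ny * nz)


def check_convergence(history, tol: float) -> bool:
    """True iff the last two mean-u_z samples differ relatively by < tol.

    A zero mean flow (fully blocked geometry) counts as converged-to-zero.
    """
    if len(history) < 2:
        return False
    prev, last = history[-2], history[-1]
    if last == 0.0:
        return prev == 0.0
    return abs(last - prev) / abs(last) < tol


def run_lbm(grid: VoxelGrid, params: LBMParams | None = None) -> FlowField:
    """Iterate the D3Q19 update to steady state on ``grid``.

    Starts from rho = 1, u = 0 everywhere and stops when the relative change
    of the domain-mean u_z over one check interval drops below
    ``convergence_tol`` (or at ``max_steps``, flagged unconverged).
    Geometries with no percolating air path along z converge to zero flow.
    """
    params = params or LBMParams()
    solid = np.ascontiguousarray(grid.occupancy.astype(np.bool_))
    nx, ny, nz = solid.shape
    f = np.empty((19, nx, ny, nz), dtype=np.float64)
    for i in range(19):
        f[i] = W[i]
    fnew = f.copy()

    history: list[float] = []
    converged = False
    steps = 0
    while steps < params.max_steps:
        for _ in range(params.check_interval):
            _step(f, fnew, solid, C, W, OPP, params.omega)
            f, fnew = fnew, f
            _apply_density_bc(f, solid, C, W,
                              params.inlet_density, params.outlet_density)
            steps += 1
        mean_uz = _mean_uz(f, solid, C)
        if not np.isfinite(mean_uz):
            raise RuntimeError(f"LBM solution diverged at step {steps}")
        history.append(mean_uz)
        if check_convergence(history, params.convergence_tol):
            converged = True
            break
    if not converged:
        logger.warning("LBM not converged after %d steps (tol=%g)",
                       steps, params.convergence_tol)

    density, velocity = _moments(f, solid, C)
    return FlowField(velocity=velocity, density=density, grid=grid,
                     params=params, converged=converged, steps_run=steps,
                     mean_uz_history=history)
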