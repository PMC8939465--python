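"""Flow-level quantities derived from a converged lattice-Boltzmann field.

Darcy's law for a porous sheet of thickness L_F and area A under a pressure
drop dp reads Q = k A dp / (mu L_F), defining the permeability k; the Darcy
(face) velocity is U = Q/A.  Because the flow is Stokes, dp is proportional
to U and the ratio I = dp/U = mu L_F / k is the breathing impedance of the
fabric.  The filtration/breathability trade-off is summarized by the figure
of merit -ln(1 - fraction filtered)/I, which is additive over identical
layers in series.

Also here: trilinear interpolation of the node velocities to a continuous
field, streamline tracing, the streamline-curvature lengthscale
Sigma = |u|^2 / |a_perp| (the local radius-of-curvature scale that controls
which particle sizes feel inertial capture), and the speed-band census of a
slice (most flux passes through a few fast inter-yarn pore voxels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from numba import njit

from .lbm import FlowField
from .scales import AIR_DYNAMIC_VISCOSITY, UnitSystem, build_units, reynolds

INFINITE_SIGMA = math.inf


@dataclass(frozen=True)
class DarcySummary:
    """Darcy's-law characterization of one geometry + flow (lattice + physical)."""

    q_lb: float            # volumetric flow per time step, lattice units
    area_lb: float         # cross-section in lattice units (nx*ny)
    u_darcy_lb: float      # Q/A
    delta_p_lb: float      # c_s^2 * density contrast
    l_f_lb: float          # fabric thickness in lattice units
    k_lb: float            # permeability, lattice units
    k_um2: float           # permeability, um^2
    reynolds: float        # Re = U L / nu at the stated lengthscale
    lengthscale_um: float
    u_darcy_m_per_s: float  # physical face velocity of the (unscaled) field


def darcy_summary(field: FlowField, lengthscale_um: float | None = None,
                  units: UnitSystem | None = None) -> DarcySummary:
    """Permeability, Darcy velocity and Reynolds number of a converged field.

    Q is measured as the mean over all z-slices of the slice-integrated u_z
    (steady-state flux is z-independent, so averaging suppresses residual
    discretization noise).  k follows from Darcy's law with the LB dynamic
    viscosity mu = rho_LB * nu_LB and the fabric thickness L_F in lattice
    units; physically k_um2 = k_lb * pitch^2.
    """
    grid = field.grid
    params = field.params
    if units is None:
        units = build_units(grid.voxel_pitch, nu_lb=params.nu_lb)
    if lengthscale_um is None:
        lengthscale_um = grid.shape[0] * grid.voxel_pitch / 2.0

    slice_flux = field.velocity[..., 2].sum(axis=(0, 1))
    q_lb = float(slice_flux.mean())
    area = float(grid.shape[0] * grid.shape[1])
    u_darcy = q_lb / area
    delta_p = params.delta_p_lb
    if delta_p <= 0:
        raise ValueError("zero driving pressure difference")
    l_f = float(grid.fabric_thickness_lattice)
    mu_lb = 1.0 * params.nu_lb  # rho_LB = 1
    k_lb = q_lb * mu_lb * l_f / (area * delta_p) if l_f > 0 else 0.0
    k_lb = max(k_lb, 0.0)
    re = reynolds(u_darcy, lengthscale_um / grid.voxel_pitch, params.nu_lb)
    return DarcySummary(
        q_lb=q_lb, area_lb=area, u_darcy_lb=u_darcy, delta_p_lb=delta_p,
        l_f_lb=l_f, k_lb=k_lb,
        k_um2=units.permeability_to_physical_um2(k_lb),
        reynolds=re, lengthscale_um=lengthscale_um,
        u_darcy_m_per_s=units.velocity_to_physical(u_darcy))


def impedance(k_um2: float, l_f_um: float,
              mu: float = AIR_DYNAMIC_VISCOSITY) -> float:
    """Breathing impedance I = mu L_F / k, in Pa s per cm of face velocity.

    Returns inf for an impermeable sheet (k = 0).
    """
    if k_um2 < 0 or l_f_um <= 0 or mu <= 0:
        raise ValueError("invalid impedance inputs")
    if k_um2 == 0:
        return math.inf
    i_si = mu * (l_f_um * 1e-6) / (k_um2 * 1e-12)   # Pa s / m
    return i_si / 100.0                              # Pa s / cm


def pressure_drop(impedance_pa_s_per_cm: float, u_cm_per_s: float) -> float:
    """dp = I U across the sheet, in Pa."""
    return impedance_pa_s_per_cm * u_cm_per_s


def pore_model_k(epsilon_by: float, d_eff_um: float) -> float:
    """Poiseuille-channel permeability model k = eps_by d_eff^2 / 32 (um^2).

    Models the fabric as straight cylindrical channels of effective diameter
    d_eff occupying an area fraction eps_by — the inter-yarn pores that
    carry essentially all of the flow.
    """
    if not (0.0 <= epsilon_by <= 1.0) or d_eff_um <= 0:
        raise ValueError("invalid pore-model inputs")
    return epsilon_by * d_eff_um ** 2 / 32.0


def figure_of_merit(fraction_filtered: float,
                    impedance_pa_s_per_cm: float) -> float:
    """Filtration per unit breathing cost: -ln(1 - f)/I (cm Pa^-1 s^-1).

    Additive over identical layers in series: doubling the layers squares
    (1 - f) and doubles I, leaving the figure of merit unchanged.
    """
    if not (0.0 <= fraction_filtered < 1.0):
        raise ValueError("fraction filtered must lie in [0, 1)")
    if impedance_pa_s_per_cm <= 0:
        raise ValueError("impedance must be positive")
    return -math.log(1.0 - fraction_filtered) / impedance_pa_s_per_cm


# -- continuous velocity field ----------------------------------------------

@njit(cache=True)
def interp_velocity_kernel(u, x, y, z):
    """Trilinear interpolation of the node velocities at one point.

    Node i sits at continuous coordinate i; x/y wrap periodically; z must
    lie within [0, nz-1].  Solid nodes hold zero velocity, so the blend
    decays linearly to zero at walls.
    """
    nx, ny, nz = u.shape[0], u.shape[1], u.shape[2]
    x = x % nx
    y = y % ny
    i0 = int(math.floor(x))
    j0 = int(math.floor(y))
    k0 = int(math.floor(z))
    fx = x - i0
    fy = y - j0
    fz = z - k0
    i1 = (i0 + 1) % nx
    j1 = (j0 + 1) % ny
    i0 = i0 % nx
    j0 = j0 % ny
    if k0 < 0 or k0 + 1 > nz - 1:
        if k0 == nz - 1 and fz == 0.0:
            k1 = k0
        else:
            raise ValueError("position outside z extent")
    else:
        k1 = k0 + 1
    out = np.zeros(3)
    for d in range(3):
        c00 = u[i0, j0, k0, d] * (1 - fx) + u[i1, j0, k0, d] * fx
        c10 = u[i0, j1, k0, d] * (1 - fx) + u[i1, j1, k0, d] * fx
        c01 = u[i0, j0, k1, d] * (1 - fx) + u[i1, j0, k1, d] * fx
        c11 = u[i0, j1, k1, d] * (1 - fx) + u[i1, j1, k1, d] * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        out[d] = c0 * (1 - fz) + c1 * fz
    return out


def interpolate_velocity(field: FlowField, position) -> np.ndarray:
    """Continuous velocity (lattice units) at ``position`` in voxel coords."""
    pos = np.asarray(position, dtype=float)
    return interp_velocity_kernel(field.velocity, pos[0], pos[1], pos[2])


# -- streamlines and curvature ----------------------------------------------

@dataclass
class Streamline:
    """Ordered path following the local flow direction."""

    points: np.ndarray        # (n, 3) voxel coordinates
    velocities: np.ndarray    # (n, 3) lattice units
    sigma: np.ndarray | None  # (n,) curvature lengthscale, voxels
    termination: str          # exit | solid | stagnation | max_length


def trace_streamline(field: FlowField, start, *, step: float = 0.25,
                     max_steps: int = 40_000,
                     compute_sigma: bool = False) -> Streamline:
    """Integrate dx/ds = u/|u| with classical RK4 from ``start``.

    The step is an arc length in voxels (<= 0.25 by default).  Terminates on
    leaving the z extent ("exit"), entering a solid voxel ("solid"),
    vanishing speed ("stagnation") or the step budget ("max_length").
    """
    occ = field.grid.occupancy
    nx, ny, nz = occ.shape
    p = np.asarray(start, dtype=float).copy()
    if occ[int(round(p[0])) % nx, int(round(p[1])) % ny,
           min(max(int(round(p[2])), 0), nz - 1)]:
        raise ValueError("streamline start lies in a solid voxel")
    u = field.velocity
    tiny = 1e-300

    def unit_vel(pos):
        v = interp_velocity_kernel(u, pos[0], pos[1], pos[2])
        s = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        return v, s

    pts, vels = [], []
    termination = "max_length"
    for _ in range(max_steps):
        try:
            v1, s1 = unit_vel(p)
        except ValueError:
            termination = "exit"
            break
        if s1 < tiny:
            termination = "stagnation"
            break
        pts.append(p.copy())
        vels.append(v1.copy())
        try:
            k1 = v1 / s1
            v2, s2 = unit_vel(p + 0.5 * step * k1)
            k2 = v2 / max(s2, tiny)
            v3, s3 = unit_vel(p + 0.5 * step * k2)
            k3 = v3 / max(s3, tiny)
            v4, s4 = unit_vel(p + step * k3)
            k4 = v4 / max(s4, tiny)
        except ValueError:
            termination = "exit"
            break
        p = p + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        p[0] %= nx
        p[1] %= ny
        if not (0.0 <= p[2] <= nz - 1):
            termination = "exit"
            break
        if occ[int(round(p[0])) % nx, int(round(p[1])) % ny,
               int(round(p[2]))]:
            termination = "solid"
            break

    pts_arr = np.array(pts) if pts else np.empty((0, 3))
    vels_arr = np.array(vels) if vels else np.empty((0, 3))
    sig = None
    if compute_sigma and len(pts) > 0:
        sig = np.array([curvature_sigma(field, q) for q in pts_arr])
    return Streamline(points=pts_arr, velocities=vels_arr, sigma=sig,
                      termination=termination)


def curvature_sigma(field: FlowField, point, h: float = 0.5) -> float:
    """Streamline-curvature lengthscale Sigma = |u|^2 / |a_perp| in voxels.

    The convective acceleration a = (u . grad) u is evaluated by central
    differences of the interpolated field (stencil half-width ``h``), and
    a_perp = a - u_hat (u_hat . a) is its component normal to the flow.
    Straight flow (a_perp = 0) returns the infinite-curvature sentinel.
    """
    u = field.velocity
    p = np.asarray(point, dtype=float)
    v = interp_velocity_kernel(u, p[0], p[1], p[2])
    speed2 = float(v @ v)
    if speed2 == 0.0:
        raise ValueError("zero velocity: Sigma undefined")
    grad = np.empty((3, 3))   # grad[k, j] = d u_j / d x_k
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        up = interp_velocity_kernel(u, *(p + dp))
        um = interp_velocity_kernel(u, *(p - dp))
        grad[k] = (up - um) / (2.0 * h)
    a = v @ grad              # a_j = sum_k u_k du_j/dx_k
    uhat = v / math.sqrt(speed2)
    a_perp = a - uhat * float(uhat @ a)
    a_perp_mag = float(np.linalg.norm(a_perp))
    if a_perp_mag == 0.0:
        return INFINITE_SIGMA
    return speed2 / a_perp_mag


# -- slice census and rescaling ---------------------------------------------

@dataclass(frozen=True)
class SpeedBands:
    """Partition of a slice's air voxels by u_z relative to the slice mean."""

    z_slice: int
    n_air: int
    n_below_mean: int
    n_mean_to_10x: int
    n_above_10x: int
    flux_fraction_above_10x: float
    mean_uz: float

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_below_mean, self.n_mean_to_10x, self.n_above_10x)


def classify_speed_bands(field: FlowField, z_slice: int) -> SpeedBands:
    """Count air voxels with u_z below the slice mean, within [mean, 10x mean],
    and above 10x the mean, plus the flux share of the fast band.

    Band edges are closed on the lower side ([mean, 10 mean]) so a uniform
    slice lands entirely in the middle band.
    """
    occ = field.grid.occupancy
    if not (0 <= z_slice < occ.shape[2]):
        raise ValueError("z_slice outside the grid")
    air = occ[:, :, z_slice] == 0
    uz = field.velocity[:, :, z_slice, 2][air]
    n_air = int(air.sum())
    if n_air == 0:
        return SpeedBands(z_slice, 0, 0, 0, 0, 0.0, 0.0)
    mean = float(uz.mean())
    below = int((uz < mean).sum())
    above = int((uz > 10.0 * mean).sum())
    middle = n_air - below - above
    total_flux = float(uz.sum())
    fast_flux = float(uz[uz > 10.0 * mean].sum())
    frac = fast_flux / total_flux if total_flux != 0 else 0.0
    return SpeedBands(z_slice, n_air, below, middle, above, frac, mean)


def rescale_flow(field: FlowField, u_target_m_per_s: float,
                 units: UnitSystem | None = None) -> FlowField:
    """Scale all node velocities so the physical face velocity is ``u_target``.

    Legitimate because the flow is Stokes: the pattern is independent of the
    driving, only the amplitude changes.  The returned field carries the
    physical velocity scale needed by the particle integrator.
    """
    if units is None:
        units = build_units(field.grid.voxel_pitch, nu_lb=field.params.nu_lb)
    u_now_lb = float(field.velocity[..., 2].mean())
    if u_now_lb == 0.0:
        raise ValueError("cannot rescale a zero-flow field")
    u_target_lb = units.velocity_to_lattice(u_target_m_per_s)
    factor = u_target_lb / u_now_lb
    return dc_replace(field, velocity=field.velocity * factor,
                      velocity_scale_m_per_s=units.velocity_scale_m_per_s)
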