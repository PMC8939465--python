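"""Lattice <-> physical unit conversion and dimensionless-number estimates.

The lattice-Boltzmann solver works in lattice units (voxel = 1, time step
= 1).  Physical scales follow from matching the kinematic viscosity: with
voxel pitch dx and lattice viscosity nu_LB, the physical time step is
dt = nu_LB dx^2 / nu_air, and one lattice velocity unit is dx/dt.

Also here: Reynolds and Peclet numbers, Stokes-Einstein diffusivity, and
the areal-density estimate of a fabric's solid volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Boltzmann as K_B

# Air and water/mucus at 20 degC, 1e5 Pa.
AIR_DYNAMIC_VISCOSITY = 1.8e-5       # Pa s
AIR_KINEMATIC_VISCOSITY = 1.5e-5     # m^2/s
AIR_DENSITY = 1.2                    # kg/m^3
WATER_DENSITY = 998.0                # kg/m^3
COTTON_DENSITY = 1500.0              # kg/m^3
DEFAULT_TEMPERATURE = 293.15         # K

# Face velocities for an ~190 cm^2 mask at typical breathing flow rates.
FLOW_SPEED_REST = 0.5e-2             # m/s
FLOW_SPEED_MILD = 1.8e-2             # m/s
FLOW_SPEED_MODERATE = 2.7e-2         # m/s
FLOW_SPEED_MAXIMAL = 7.5e-2          # m/s


@dataclass(frozen=True)
class UnitSystem:
    """Physical meaning of lattice units for one simulation.

    Attributes
    ----------
    dx_um : voxel pitch in micrometers.
    nu_lb : lattice kinematic viscosity (1/6 for relaxation rate 1).
    nu_phys : physical kinematic viscosity in m^2/s.
    """

    dx_um: float
    nu_lb: float = 1.0 / 6.0
    nu_phys: float = AIR_KINEMATIC_VISCOSITY

    def __post_init__(self) -> None:
        if min(self.dx_um, self.nu_lb, self.nu_phys) <= 0:
            raise ValueError("all unit-system inputs must be positive")

    @property
    def dx_m(self) -> float:
        return self.dx_um * 1e-6

    @property
    def dt_s(self) -> float:
        """Physical duration of one lattice time step (viscosity matching)."""
        return self.nu_lb * self.dx_m ** 2 / self.nu_phys

    @property
    def velocity_scale_m_per_s(self) -> float:
        """Physical speed of one lattice velocity unit, dx/dt."""
        return self.dx_m / self.dt_s

    # conversions -----------------------------------------------------------

    def velocity_to_physical(self, u_lb: float) -> float:
        return u_lb * self.velocity_scale_m_per_s

    def velocity_to_lattice(self, u_m_per_s: float) -> float:
        return u_m_per_s / self.velocity_scale_m_per_s

    def length_to_physical_um(self, l_lb: float) -> float:
        return l_lb * self.dx_um

    def length_to_lattice(self, l_um: float) -> float:
        return l_um / self.dx_um

    def permeability_to_physical_um2(self, k_lb: float) -> float:
        """Darcy permeability: k_phys = k_LB * dx^2."""
        return k_lb * self.dx_um ** 2

    def permeability_to_lattice(self, k_um2: float) -> float:
        return k_um2 / self.dx_um ** 2

    def pressure_to_physical_pa(self, p_lb: float) -> float:
        """p_phys = p_LB * rho_air * (dx/dt)^2 (LB mass density is 1)."""
        return p_lb * AIR_DENSITY * self.velocity_scale_m_per_s ** 2

    def pressure_to_lattice(self, p_pa: float) -> float:
        return p_pa / (AIR_DENSITY * self.velocity_scale_m_per_s ** 2)


def build_units(dx_um: float, nu_lb: float = 1.0 / 6.0,
                nu_phys: float = AIR_KINEMATIC_VISCOSITY) -> UnitSystem:
    """Construct a :class:`UnitSystem` from voxel pitch and viscosities."""
    return UnitSystem(dx_um=dx_um, nu_lb=nu_lb, nu_phys=nu_phys)


def reynolds(speed: float, lengthscale: float, kinematic_viscosity: float) -> float:
    """Re = U L / nu (any consistent unit system)."""
    if lengthscale <= 0 or kinematic_viscosity <= 0:
        raise ValueError("lengthscale and viscosity must be positive")
    return speed * lengthscale / kinematic_viscosity


def stokes_einstein_diffusivity(d_p_m: float,
                                temperature_k: float = DEFAULT_TEMPERATURE,
                                mu: float = AIR_DYNAMIC_VISCOSITY) -> float:
    """Brownian diffusivity D = k_B T / (3 pi mu d_p) in m^2/s."""
    import math
    if min(d_p_m, temperature_k, mu) <= 0:
        raise ValueError("inputs must be positive")
    return K_B * temperature_k / (3.0 * math.pi * mu * d_p_m)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Order-of-magnitude comparison of diffusive capture vs advection.

    t_dx is the time to diffuse across an inter-yarn pore (width^2 / D);
    t_a the time to be advected through the fabric (depth / U).  Their
    ratio is the Peclet number: Pe >> 1 means particles are swept through
    far faster than they can diffuse to a pore wall, so capture by
    diffusion is negligible.
    """

    d_p_m: float
    diffusivity_m2_per_s: float
    t_dx_s: float
    t_a_s: float

    @property
    def peclet(self) -> float:
        return self.t_dx_s / self.t_a_s


def peclet(pore_width_m: float, fabric_depth_m: float, speed_m_per_s: float,
           diffusivity_m2_per_s: float, d_p_m: float = 100e-9) -> DiffusionEstimate:
    """Diffusion-vs-advection estimate for a pore/fabric/flow combination."""
    if min(pore_width_m, fabric_depth_m, speed_m_per_s,
           diffusivity_m2_per_s) <= 0:
        raise ValueError("inputs must be positive")
    t_dx = pore_width_m ** 2 / diffusivity_m2_per_s
    t_a = fabric_depth_m / speed_m_per_s
    return DiffusionEstimate(d_p_m=d_p_m,
                             diffusivity_m2_per_s=diffusivity_m2_per_s,
                             t_dx_s=t_dx, t_a_s=t_a)


def areal_solid_fraction(mass_per_area_kg_m2: float, material_density_kg_m3: float,
                         thickness_m: float) -> float:
    """Solid volume fraction of a sheet from its areal density.

    E.g. 120 g/m^2 of cotton (1500 kg/m^3) spread over a 285 um thickness
    is about 28% solid by volume.
    """
    if min(mass_per_area_kg_m2, material_density_kg_m3, thickness_m) <= 0:
        raise ValueError("inputs must be positive")
    return mass_per_area_kg_m2 / (material_density_kg_m3 * thickness_m)
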