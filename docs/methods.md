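# Methods

## Model overview

`weavefilter` treats a woven fabric mask as a porous medium at two
lengthscales — fibers (~10–20 µm) and yarns (hundreds of µm) — and asks two
questions: how hard is it to breathe through (impedance), and what fraction
of exhaled droplets does it capture (filtration efficiency)?  The chain is
geometry → steady Stokes air flow → droplet trajectories → flow-weighted
capture statistics.  Electrostatics, droplet evaporation, Brownian-dynamics
trajectories, and two-way particle–flow coupling are all out of scope; the
diffusion channel is handled only as a Péclet-number estimate.

## Geometry

### Voxel grids

All stages consume a `VoxelGrid`: a strictly binary occupancy array
(1 = fiber) on a cubic lattice with a physical pitch in µm.  `z` is the
breathing direction; `x`/`y` are in-plane and treated as periodic
everywhere (flow solver, interpolation, particle wrap-around, distance
fields).  A voxel `(i, j, k)` is the unit cube centered at integer
coordinates in the continuous voxel frame, so its faces lie at half-integer
coordinates; with bounce-back walls the effective no-slip surface also lies
half a voxel beyond the outermost fluid node, making the two conventions
consistent wherever geometric error is assessed.

### Image segmentation

A grayscale confocal stack becomes a grid in four ordered steps: (i) zero
the intensity of the lowest-quality bottom slices (default 10; they are
zeroed in place, not removed, so array depth is preserved); (ii) pad with
all-zero slices on both ends (default 200 per side) so the simulation box
contains the approach and exit flow; (iii) separable 3D Gaussian blur
(default σ = 1 voxel, zero-value boundary, consistent with the stack being
embedded in air); (iv) binarize at a fixed threshold (default 10) and
delete 26-connected components of ≤ 25 voxels.  The pipeline is linear up
to binarization, so scaling intensities and threshold together is a no-op
(tested).  Woven fabric must be a single connected structure, so after the
cluster filter nearly all solid voxels belong to one component; the test
suite asserts > 90% on synthetic weaves.  The threshold is the dominant
volume uncertainty (order 10% over a ±50% threshold range);
`threshold_sensitivity` reports it but nothing asserts on it.

### Synthetic plain weave

The generator builds a periodic 2×2-unit-cell patch: yarns of elliptical
cross-section whose centerlines undulate sinusoidally in z with amplitude
= yarn_thickness/2 and period twice the crossing lattice constant, warp and
weft phase-offset so that at each crossing one yarn passes over and the
other under (centerline separation exactly one yarn thickness — surfaces
touch, never overlap, at unit scale).  This is the simplest topology with
plain-weave interlacing; the real fabric's yarn cross-section is unknown,
so no claim is made beyond matched summary statistics (lattice constants,
solid fraction, pore scale, TPI).  The cross-section is scaled by a single
bisection-tuned multiplier until the solid fraction inside the fabric
z-range lands within ±0.05 (practically ±0.02) of the target; an
unreachable target raises.  Stray fibers — straight cylinders with
diameters drawn from a truncated normal (16.7 ± 4.8 µm by default) —
bridge random chords of each inter-yarn pore at random heights; they model
the partial obstruction of pore channels that drives interception capture.
A voxel is solid iff its center lies inside an implicit surface, which
makes voxel counts directly comparable to Monte-Carlo integrals of the
same surfaces (tested to 2%).

Defaults describe the imaged cotton fabric: 297 × 252 µm yarn lattice
(186 threads per inch), 69% solid inside the fabric, 93.6 µm usable
thickness, 1.8 µm voxels.  Test and example geometries are the same weave
scaled coarser (4–7 µm voxels, 120–160 µm lattice constants, 55–60% solid)
so that pores stay several voxels wide while lattice sizes stay at
desk scale; these sizes are the package's own choice of test conditions
and are noted where used.

## Flow solver

Single-relaxation-time (BGK) lattice Boltzmann on the D3Q19 stencil,
weights {1/3, 1/18, 1/36}, c_s² = 1/3.  Relaxation rate ω = 1 by default,
giving lattice viscosity ν_LB = c_s²(1/ω − 1/2) = 1/6.  Fiber voxels apply
full-way on-site bounce-back (population reversal), fluid voxels BGK
collision; both then stream.  Boundaries: periodic in x/y; on the first and
last z-slices all populations are set after streaming to the equilibrium at
a prescribed density with the velocity copied from the adjacent interior
node.  The default contrast 1 ± 10⁻⁵ drives the flow at Re ≪ 1 (asserted
< 0.1), so the flow pattern is independent of the driving and can be
rescaled freely.  The driving pressure difference is Δp = c_s²Δρ =
(2/3)×10⁻⁵ in lattice units for the default contrast.

Initialization is ρ = 1, u = 0.  Convergence is declared when the relative
change of the domain-mean u_z over one check interval (default 100 steps)
falls below 10⁻⁷ — two orders below the driving contrast; a fully blocked
geometry converges to zero flow.  Validation: plane-Poiseuille profile and
amplitude to < 2% at a 20-node channel, slice-flux constancy to < 0.5%,
flow linearity under doubled driving to < 1%.  Tests on weave geometries
relax the tolerance to 10⁻⁶, which moves the measured Darcy velocity by
well under the assertion margins.

## Darcy layer and unit system

Q is the mean over z-slices of the slice-integrated u_z (flux constancy
makes the mean a noise reduction, not a model choice).  Permeability
follows Darcy's law with the LB dynamic viscosity µ = ρ_LB ν_LB and the
fabric thickness L_F in lattice units; physically k_µm² = k_LB·pitch².
Impedance I = µ_air L_F/k is reported in Pa s cm⁻¹; Δp = I·U.  The
pore model k = ε d²/32 idealizes the pores as developed Poiseuille
channels; on a short voxelized pore the measured k is lower by entrance
effects, and the test suite checks it against the series combination of
channel resistance 128µL/(πd⁴) and Sampson orifice resistance 24µ/d³
(15%), keeping the bare model as an order-of-magnitude bound.

Physical units come from viscosity matching: Δt = ν_LB Δx²/ν_air, so one
lattice velocity unit is Δx/Δt (50 m/s at 1.8 µm pitch).  Because the flow
is Stokes, `rescale_flow` multiplies the whole field by one scalar so the
physical face velocity equals a target (default 2.7 cm/s, the
moderate-exertion breathing speed for a ~190 cm² mask); permeability is
invariant under this rescaling.

## Streamlines and curvature

The node field is made continuous by trilinear interpolation (solid nodes
contribute zero, so speed decays linearly to walls; exact on linear fields,
bounded by corner extremes).  Streamlines integrate dx/ds = u/|u| with
classical RK4 at ≤ 0.25 voxel arc steps, terminating on domain exit, solid
entry, stagnation, or a step budget.  The curvature lengthscale
Σ = |u|²/|a⊥| with a = (u·∇)u from central differences at half-voxel
stencil and a⊥ = a − û(û·a); straight flow returns an infinite sentinel.
Σ is the local radius-of-curvature scale of the flow and sets the obstacle
size entering the Stokes number: rigid rotation gives Σ = r exactly
(the stencil is exact on linear fields), and on weave flows Σ sits in the
pore-to-yarn range of tens to hundreds of µm — which is why inertial
capture is weak for breath-sized droplets.

## Particle transport

Droplets are spheres with the density of water (998 kg/m³) coupled to the
air only through Stokes drag with drag time t_I = ρ_p d_p² C/(18µ); the
Cunningham slip factor is fixed at C = 1 (within 15% of unity for
d_p ≥ 1 µm, the validity floor set by the 1.8 µm imaging resolution) but
lives in `ParticleSpec` so a slip formula can be injected.  The integrator
is exponential (exact for piecewise-constant u): per step, with u frozen,
v ← u + (v−u)e^(−Δt/t_I) and the position advances by the exact integral
of that velocity.  Steps satisfy Δt ≤ min(0.1 t_I, 0.25 voxel advection
time) in inertial mode; tracer mode advects along u in quarter-voxel steps
(the zero-Stokes interception limit).  Both step controls are adjustable;
the t_I → 0 convergence test refines both modes to 0.05-voxel steps so the
comparison isolates inertia from step-size error.

Capture is interception contact: the droplet center comes within d_p/2 of
the union-of-cubes fiber surface.  The test is exact — a certified lower
bound from a precomputed (periodic-aware) Euclidean distance transform
short-circuits far-from-wall steps, and an exact point-to-cube scan decides
close encounters; the flag matches a brute-force oracle over random
configurations.  The sensitivity of efficiency to the contact rule (a
±half-voxel question at the imaging resolution) is of the same order as
the factor-two uncertainty a voxelized surface imposes anyway; results at
d_p near the voxel pitch should be read with that in mind.

Seeding covers the central quarter of the x/y area (one unit cell of a
2×2-cell patch) with a uniform √N×√N grid, 20 voxels upstream of the first
fabric slice; the initial particle velocity is the local fluid velocity.
A trajectory ends captured (contact), penetrated (20 voxels past the last
fabric slice), or unresolved (step budget 10⁶, or washed out upstream);
unresolved trajectories are excluded with a warning.  Efficiency weights
every trajectory by the fluid u_z at its seed, so it is the captured
fraction of the sampled aerosol flux — uniform aerosol concentration means
fast channels carry proportionally more droplets.  The reference sample
size is N = 1600 (40×40); tests use 400 with a refinement check against
1600.

## Numerical and design choices

- Tie-breaks: speed-band classification uses [mean, 10·mean] closed on the
  lower side, so a uniform slice is entirely in the middle band.
- Degenerate inputs: zero yarn width → all-air grid; blocked geometry →
  converged zero flow, k = 0, infinite impedance; zero total seed flux →
  explicit error rather than 0/0.
- Determinism: the weave generator is seeded; the solver and integrator
  have no stochastic elements, so a fixed config reproduces output files
  byte-for-byte.
- Config validation is by dataclass invariants plus explicit key checking;
  YAML configs reject unknown keys.
- VTK export is legacy-ASCII structured points (text), alongside TIFF
  stacks with JSON sidecars for pitch metadata.

## What the synthetic generator does and does not show

The generator reproduces the features that control the physics — two
lengthscales, interlaced topology, pore channels partially obstructed by
stray fibers, a matched solid fraction — but not fiber-level texture:
yarns are smooth ellipses rather than twisted fiber bundles, intra-yarn
porosity is absent (consistent with the flow solver's finding that
sub-µm intra-yarn gaps carry negligible flow), and disorder is limited to
the stray fibers.  Passing tests on synthetic weaves therefore validate
the solver, the transport integrator, and the monotone size-dependence of
interception capture; they do not certify absolute efficiencies for any
particular real fabric, which depend on imaged geometry and carry a
factor-two model uncertainty.

## Problem sizes

The shipped tests run, on one core, LBM steady states on lattices between
24×4×41 (channel) and 48×48×30 (weave), a 32×32×40 pore plate (twice, for
linearity), and filtration sweeps of 4 diameters × 2 modes × 400 seeds plus
a 1600-seed refinement point; the full suite completes in a few minutes.
The same code runs imaged-fabric lattices (hundreds of voxels per side,
~4×10⁷ sites) unchanged, but reaching a steady state on lattices of
millions of sites is a matter of hours on a single core with the shipped
kernel — the solver is written for correctness and portability, not
large-scale throughput.
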