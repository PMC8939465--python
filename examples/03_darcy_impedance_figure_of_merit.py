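"""Breathability analysis of the imaged cotton fabric from its permeability.

Starting from the measured permeability of the confocal-imaged fabric
(k = 0.73 lattice units on a 1.8 um grid) this script derives the numbers
a mask designer cares about: impedance, pressure drop while breathing, and
the filtration-per-breathing-cost figure of merit.
"""

import weavefilter as wf

units = wf.build_units(1.8)
k_um2 = units.permeability_to_physical_um2(0.73)
l_f_um = 52 * 1.8   # usable imaged thickness

imped = wf.impedance(k_um2, l_f_um)
dp = wf.pressure_drop(imped, 2.7)

print(f"permeability: 0.73 lattice units = {k_um2:.2f} um^2")
print(f"impedance I = mu L_F / k = {imped:.2f} Pa s/cm")
print(f"pressure drop at 2.7 cm/s (moderate exertion): {dp:.1f} Pa")
print(f"pore model (eps=0.1, d_eff=50 um): k ~ {wf.pore_model_k(0.1, 50.0):.1f} um^2")

fom = wf.figure_of_merit(0.05, imped)
fom_n95 = wf.figure_of_merit(0.95, 30.0)
print(f"figure of merit at 5% capture: {fom:.4f} cm/(Pa s)")
print(f"figure of merit needed for 95% capture at the N95 impedance cap "
      f"(30 Pa s/cm): {fom_n95:.3f} cm/(Pa s)")
# The fabric breathes easily (~1/4 of the N95 impedance limit) but captures
# so little that its figure of merit is more than ten times too small for
# respirator-grade filtration; stacking identical layers does not change
# the figure of merit.
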