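"""Physical constants in the internal unit system (kJ/mol, nm, ps, bar, K, u).

The internal units follow the common biomolecular-simulation convention:
energies in kJ/mol, lengths in nm, times in ps, masses in unified atomic
mass units, pressures in bar, temperatures in K.  A pleasant consequence is
that 1 u (nm/ps)^2 = 1 kJ/mol exactly, so kinetic energies need no
conversion factor.
"""

#: Boltzmann constant in kJ/mol/K (CODATA 2018, exact SI definition).
KB = 0.008314462618

#: Avogadro constant in 1/mol (exact SI definition).
N_AVOGADRO = 6.02214076e23

#: Conversion of bar*nm^3 to kJ/mol: 1e5 Pa * 1e-27 m^3 * N_A / 1000.
BAR_NM3_TO_KJ_PER_MOL = 1e5 * 1e-27 * N_AVOGADRO / 1000.0

#: Thermochemical calorie, kJ per kcal.
KCAL_TO_KJ = 4.184
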