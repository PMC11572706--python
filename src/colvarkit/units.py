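"""Unit system and physical constants.

The toy engine works in the AKMA-like unit set common to biomolecular codes:
lengths in angstrom, time in femtoseconds, masses in atomic mass units and
energies in kcal/mol.  Temperatures are in kelvin and friction coefficients
are given in 1/ps (converted internally to 1/fs).
"""

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL_MOL_K = 0.0019872041

#: Conversion factor turning (kcal/mol/angstrom)/amu into angstrom/fs**2.
#: Derived from 1 kcal = 4184 J and 1 amu = 1e-3 kg/mol.
ACC_KCAL_PER_AMU_A = 4.184e-4

#: Friction input unit (1/ps) expressed in 1/fs.
INV_PS_TO_INV_FS = 1.0e-3
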