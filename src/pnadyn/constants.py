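"""Physical constants and unit conversions.

Internal units follow the GROMACS convention: lengths in nm, times in ps,
energies in kJ/mol, masses in amu (g/mol).  kcal/mol appears only at
reporting boundaries.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.008314462618

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184

#: Angstrom per nm
ANGSTROM_PER_NM = 10.0
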