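"""Physical constants and unit conversions used across the package.

Internal units: lengths in Angstrom, energies in kcal/mol, charges in
elementary charge units (e), masses in amu, temperatures in Kelvin.
"""

import scipy.constants as _sc

#: Coulomb constant in kcal*Angstrom/(mol*e^2).
COULOMB_KCAL = 332.0636

#: kcal/mol per Joule/mol
KCAL_PER_J_MOL = 1.0 / 4184.0

#: Gas constant in kcal/(mol*K)
R_KCAL = _sc.R * KCAL_PER_J_MOL

#: Boltzmann constant (J/K), Planck constant (J*s), speed of light (cm/s)
KB_J = _sc.k
H_J = _sc.h
C_CM = _sc.c * 100.0
AVOGADRO = _sc.N_A

#: amu in kg
AMU_KG = _sc.atomic_mass

#: standard pressure for translational entropy (Pa)
P_STANDARD = 101325.0

#: conversion of a mass-weighted Hessian eigenvalue in kcal/(mol*A^2*amu)
#: to an angular frequency squared in s^-2
EIGVAL_TO_OMEGA2 = 4184.0 / (AVOGADRO * 1e-20 * AMU_KG)
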