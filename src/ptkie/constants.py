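"""Physical constants used throughout the package.

Pressure-dependence work in this field quotes activation volumes in
cm^3/mol, compressibilities in cm^3/(mol*kbar) and pressures in bar, so the
gas constant is carried in two unit systems: SI (J/(mol*K)) for thermal
(Eyring/Arrhenius) terms and cm^3*bar/(mol*K) for pressure terms.
"""

import scipy.constants as _sc

#: Boltzmann constant (J/K), CODATA.
KB = _sc.k

#: Planck constant (J*s), CODATA.
H = _sc.h

#: Reduced Planck constant (J*s), CODATA.
HBAR = _sc.hbar

#: Gas constant (J/(mol*K)), CODATA.
R_J = _sc.R

#: Gas constant in kJ/(mol*K), for molar energies quoted in kJ/mol.
R_KJ = _sc.R * 1e-3

#: Gas constant in cm^3*bar/(mol*K): 1 J = 10 cm^3*bar.
R_CM3_BAR = _sc.R * 10.0

#: Default temperature (K); high-pressure photolysis work is done at 25 C.
T_DEFAULT = 298.15
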