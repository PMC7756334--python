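"""Physical constants and the SPC water parameter set.

Unit system: length nm, time ps, mass u, charge e, energy kJ/mol.
Derived units: velocity nm/ps, force kJ mol^-1 nm^-1, pressure kJ mol^-1 nm^-3.
"""

import math

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_ELEC = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 8.31446e-3

#: 1 atm expressed in kJ mol^-1 nm^-3.
ATM = 0.0610194

#: 1 u / nm^3 expressed in kg / m^3 (for mass-density checks).
U_PER_NM3_TO_KG_PER_M3 = 1.66054

# --- SPC rigid 3-site water ------------------------------------------------
SPC_Q_O = -0.82           # e
SPC_Q_H = 0.41            # e
SPC_M_O = 15.9994         # u
SPC_M_H = 1.008           # u
SPC_D_OH = 0.1            # nm
#: H-O-H angle of 109.47 deg gives the H-H constraint length.
SPC_D_HH = 2.0 * SPC_D_OH * math.sin(math.radians(109.47 / 2.0))
#: O-O Lennard-Jones parameters, kJ mol^-1 nm^6 / nm^12.
SPC_C6_OO = 2.61735e-3
SPC_C12_OO = 2.634129e-6
SPC_MOLAR_MASS = SPC_M_O + 2.0 * SPC_M_H
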