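"""Physical constants and unit conversions used throughout the package.

All geometric coordinates are in micrometres, energies per nucleon in
MeV/u, single energy deposits in eV, stopping powers in keV/um, doses in
Gy.  Liquid water at unit density (1 g/cm^3) is the transport medium.
"""

#: Atomic mass unit rest energy (MeV).  Kinetic energy per nucleon E and
#: the relativistic velocity beta are related through this rest energy.
AMU_MEV = 931.494

#: Electron rest energy (MeV).
ELECTRON_MEV = 0.511

#: Bethe constant K = 4 pi N_A r_e^2 m_e c^2 (MeV cm^2 / mol).
BETHE_K = 0.307075

#: Z/A of liquid water (10 electrons / 18.0153 g per mol).
WATER_Z_OVER_A = 10.0 / 18.0153

#: Mean excitation energy of liquid water (eV).
WATER_I_EV = 75.0

#: Density of liquid water (g/cm^3).
WATER_DENSITY = 1.0

#: eV -> Joule.
EV_TO_J = 1.602176634e-19

#: Mass of 1 um^3 of unit-density water (kg).
KG_PER_UM3 = 1.0e-15

#: Dose [Gy] = LET_COEFF * LET [keV/um] * fluence [um^-2] in unit-density
#: water; equivalently 1 keV deposited in 1 um^3 gives 0.1602 Gy.
LET_COEFF = 0.1602

#: Constant of the Barkas effective-charge formula
#: Z_eff = Z (1 - exp(-BARKAS_CONST * beta * Z**BARKAS_EXP)).
BARKAS_CONST = 125.0
BARKAS_EXP = -2.0 / 3.0

#: Low-velocity limit of (Z_eff/beta)^2 for Z = 1: BARKAS_CONST squared.
ZEFF_BETA_SQ_LIMIT = BARKAS_CONST**2
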