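"""Physical constants and unit conversions (CODATA 2018).

Internal units: length Å, charge e, energy kJ/mol, field MV/cm,
wavenumber cm⁻¹, time ps, absorbance mOD.
"""

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
COULOMB_CONSTANT_SI = 8.9875517862e9  # V m / C  (1 / 4πε0)
PLANCK = 6.62607015e-34  # J s
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm/s
AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN_KJMOL = 8.31446261815324e-3  # kJ/(mol K)

# Coulomb energy prefactor: U = KE_COULOMB * q1*q2 / r  [kJ/mol, e, Å]
KE_COULOMB = 1389.35457644382  # kJ Å / (mol e²)

# Field prefactor: E = KE_FIELD * q / r²  [MV/cm, e, Å]
# = (e / 4πε0) / (1 Å)² expressed in MV/cm
KE_FIELD = COULOMB_CONSTANT_SI * ELEMENTARY_CHARGE / 1e-20 / 1e8  # 1439.96 MV/cm

# Default molar heat capacity of liquid water, J/(mol K)
WATER_CP_MOLAR = 75.3
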