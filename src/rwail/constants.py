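"""Physical constants and unit conversions.

Internal unit system: kcal/mol (energy), Å (length), ps (time),
e (charge), amu = g/mol (mass), K (temperature).  Conversions to SI
happen only at reporting/export boundaries (properties, io).
"""

import math

# CODATA-2018 based
AVOGADRO = 6.02214076e23          # 1/mol
KB_J = 1.380649e-23               # J/K
R_J = KB_J * AVOGADRO             # J/(mol K)
CAL = 4.184                       # J per thermochemical calorie (exact)

# Boltzmann constant in internal energy units
KB = R_J / (CAL * 1000.0)         # kcal/(mol K) = 0.0019872...

# Coulomb constant e^2/(4 pi eps0) in kcal Å / (mol e^2)
ELEMENTARY_CHARGE = 1.602176634e-19   # C
EPS0 = 8.8541878128e-12               # F/m
COULOMB = (ELEMENTARY_CHARGE ** 2 * AVOGADRO
           / (4.0 * math.pi * EPS0 * 1e-10 * CAL * 1000.0))  # ≈ 332.0637

# acceleration: (kcal/mol/Å) / amu -> Å/ps^2
FORCE_TO_ACC = CAL * 100.0        # = 418.4 exactly

# pressure: (kcal/mol)/Å^3 -> bar
# kcal/mol/Å^3 = 4184 J / (6.022e23 * 1e-30 m^3) = 6.9477e4 bar
P_INTERNAL_TO_BAR = CAL * 1000.0 / AVOGADRO / 1e-30 / 1e5

# masses (amu)
MASS_O = 15.999
MASS_H = 1.008
MASS_WATER = MASS_O + 2.0 * MASS_H

# dipole: e·Å -> Debye
EA_TO_DEBYE = ELEMENTARY_CHARGE * 1e-10 / 3.33564e-30

# kcal/mol -> kJ/mol
KCAL_TO_KJ = CAL

# water molar mass (g/mol) for density conversions
WATER_MOLAR_MASS = MASS_WATER

# Å^3 per molecule -> kg/m^3 for water
def water_density_kg_m3(volume_A3_per_molecule: float) -> float:
    """Mass density of water given volume per molecule in Å³."""
    return WATER_MOLAR_MASS / AVOGADRO / 1e3 / (volume_A3_per_molecule * 1e-30)
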