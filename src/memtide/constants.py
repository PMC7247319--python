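"""Physical constants (CODATA 2018) and shared defaults."""

# Elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19
# Faraday constant, C/mol
FARADAY = 96485.33212
# Molar gas constant, J/mol/K
GAS_CONSTANT = 8.314462618
# Vacuum permittivity, F/m
VACUUM_PERMITTIVITY = 8.8541878128e-12
# Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

# Defaults for aqueous work near room temperature
DEFAULT_TEMPERATURE = 298.15      # K
DEFAULT_EPS_R = 78.5              # relative permittivity of water
DEFAULT_VISCOSITY = 0.89e-3       # Pa s
DEFAULT_SHEAR_PLANE = 2.0e-10     # m (2 Angstrom)

# Molarity of pure water, used by the water-normalized partition convention
WATER_MOLARITY = 55.3             # M

ANGSTROM2_TO_M2 = 1e-20
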