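"""Physical constants and unit conversions.

Internal energy unit is kJ/mol (the GROMACS convention); kcal/mol is a
reporting unit obtained with the exact definition 1 kcal = 4.184 kJ.
Entropy computations run in SI internally (kg, m, J) and report per mole.
"""

#: Boltzmann constant in kJ/(mol K) (GROMACS value).
KB_KJ_MOL = 0.0083144621

#: Molar gas constant in J/(mol K), consistent with KB_KJ_MOL.
R_J_MOL_K = 8.3144621

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant in J/K, consistent with R_J_MOL_K.
KB_SI = R_J_MOL_K / N_AVOGADRO

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: Atomic mass unit in kg.
AMU_KG = 1.66053906660e-27

#: Nanometre in metres.
NM_M = 1e-9

#: Thermochemical kilocalorie in kilojoules (exact).
KCAL_TO_KJ = 4.184

#: Thermochemical kilocalorie in joules (exact).
KCAL_TO_J = 4184.0

#: Standard-state volume (1/c0 for c0 = 1 mol/L) in nm^3.
STANDARD_VOLUME_NM3 = 1.6605


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ.

    Raises ``ValueError`` for non-positive temperature.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KJ_MOL * temperature)


def kt_kj(temperature: float) -> float:
    """Thermal energy k_B T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJ_MOL * temperature
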