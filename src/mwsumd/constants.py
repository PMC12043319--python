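"""Physical constants and the package's unit system.

Internal units follow the AKMA-like convention used throughout:

* length      Å
* time        ps
* mass        amu (g/mol)
* temperature K
* energy      kcal/mol (potentials), amu·Å²/ps² (kinetic terms)

1 kcal/mol = 418.4 amu·Å²/ps², so velocities drawn with variance
``KB_AKMA * T / m`` are directly in Å/ps.
"""

# Boltzmann constant in kcal/mol/K (CODATA k_B * N_A / 4184)
KB_KCAL: float = 1.987204259e-3

# kcal/mol expressed in amu·Å²/ps²
KCAL_TO_AKMA: float = 418.4

# Boltzmann constant in amu·Å²/ps²/K (equals the gas constant R in these units)
KB_AKMA: float = KB_KCAL * KCAL_TO_AKMA

#: Atomic masses (amu) for elements the PDB reader may encounter.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}
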