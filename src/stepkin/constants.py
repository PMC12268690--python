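"""Physical constants and the pinned atomic-weight table.

All user-facing energies in this package are molar (J/mol) and use the
gas constant ``R_GAS``; conversions to per-molecule quantities (via
``N_AVOGADRO``) happen internally where a formula is written per molecule.
"""

R_GAS = 8.314462618  # J mol^-1 K^-1 (CODATA 2018, exact)
N_AVOGADRO = 6.02214076e23  # mol^-1 (exact)
BOLTZMANN = R_GAS / N_AVOGADRO  # J K^-1

#: Standard atomic weights, IUPAC 2021 abridged to five significant figures.
#: Pinned here so molecular weights are stable across environments.
ATOMIC_WEIGHTS = {
    "H": 1.0080,
    "He": 4.0026,
    "Li": 6.9400,
    "B": 10.810,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.060,
    "Cl": 35.450,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.380,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.90,
}
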