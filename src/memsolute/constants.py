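"""Physical constants and unit conventions.

All coordinates are in nm, trajectory times in ps, energies in kJ/mol.
Dwell/residence times at the event scale are expressed in ns where noted.
"""

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ_MOL_K = 8.314462618e-3

#: Default simulation temperature, K (body temperature).
DEFAULT_TEMPERATURE = 310.15

#: Electron counts per element, used for electron-density weighting.
ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "Na": 11, "P": 15,
    "S": 16, "CL": 17, "Cl": 17, "GD": 64, "Gd": 64,
}

#: Atomic masses (amu) for the elements used by the synthetic builders.
MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Na": 22.990,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Gd": 157.25,
}


def rt(temperature: float) -> float:
    """R*T in kJ/mol at the given temperature in K."""
    return R_KJ_MOL_K * temperature
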