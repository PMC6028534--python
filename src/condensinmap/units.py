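"""Unit conventions and conversion constants.

Concentrations are nM, volumes µm³, lengths nm (images) or µm
(chromatid axes), counts in molecules.
"""

AVOGADRO = 6.02214076e23  # 1/mol

#: molecules per (nM * µm³): 1e-9 mol/L * 1e-15 L * N_A
NM_UM3_TO_MOLECULES = 1e-9 * 1e-15 * AVOGADRO


def molecules_from_conc(conc_nM: float, volume_um3: float) -> float:
    return conc_nM * volume_um3 * NM_UM3_TO_MOLECULES


def conc_from_molecules(n_molecules: float, volume_um3: float) -> float:
    return n_molecules / (volume_um3 * NM_UM3_TO_MOLECULES)
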