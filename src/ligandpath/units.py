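"""Unit system and physical constants.

The package works in MD "academic" units throughout: length in Å, time in
ps, mass in amu, energy in kcal/mol, charge in elementary charges e.
Forces are kcal/mol/Å internally and convertible to pN for reporting,
matching the convention of steered-MD literature which quotes spring
constants in pN/Å and pulling speeds in m/s.
"""

# 1 kcal/mol/Å expressed in pN (per molecule).
KCAL_PER_MOL_ANG_TO_PN: float = 69.479
PN_TO_KCAL_PER_MOL_ANG: float = 1.0 / KCAL_PER_MOL_ANG_TO_PN

# Coulomb constant in kcal·Å/(mol·e²), the CHARMM value.
COULOMB_K: float = 332.0636

# Boltzmann constant, kcal/(mol·K).
KB: float = 0.0019872041

# Acceleration conversion: (kcal/mol/Å) / amu -> Å/ps².
# 1 kcal/mol = 418.4 amu·Å²/ps².
KCAL_TO_AKMA: float = 418.4

# Pulling speeds: 1 m/s = 1e10 Å / 1e12 ps = 0.01 Å/ps, exact.
M_PER_S_TO_ANG_PER_PS: float = 0.01


def force_to_pn(f_kcal_mol_ang):
    """Convert force from kcal/mol/Å to pN."""
    return f_kcal_mol_ang * KCAL_PER_MOL_ANG_TO_PN


def force_to_kcal(f_pn):
    """Convert force from pN to kcal/mol/Å."""
    return f_pn * PN_TO_KCAL_PER_MOL_ANG


def work_pn_ang_to_kcal(w_pn_ang):
    """Convert work from pN·Å to kcal/mol (1 kcal/mol = 69.479 pN·Å)."""
    return w_pn_ang / KCAL_PER_MOL_ANG_TO_PN


def work_kcal_to_pn_ang(w_kcal):
    """Convert work from kcal/mol to pN·Å."""
    return w_kcal * KCAL_PER_MOL_ANG_TO_PN
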