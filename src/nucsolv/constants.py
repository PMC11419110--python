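"""Physical constants for neutron-contrast calculations on nucleic acids.

All coherent scattering lengths are in fm (1 fm = 1e-5 Å), atomic masses in
Da, densities in g/cm³ at 20 °C, and scattering length densities (SLDs) in
units of 1e-6 Å⁻² throughout the package.  The literature usually quotes
biomolecular SLDs with the 1e-6 factor silently dropped ("6.36 Å⁻²" for pure
D₂O); every SLD printed or returned here carries that implicit factor.

This module is the single source for all scattering lengths, masses and
displaced atomic volumes — no numeric literals for these appear elsewhere.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

# Bound coherent neutron scattering lengths, fm (Sears tabulation).
COHERENT_B = {
    "H": -3.7406,
    "D": 6.671,
    "C": 6.6511,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
}

# Atomic masses, Da.
ATOMIC_MASS = {
    "H": 1.00794,
    "D": 2.014102,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
}

# Solvent mass densities at 20 °C, g/cm³.
DENSITY_H2O = 0.99707
DENSITY_D2O = 1.1044

# Partial specific volume of RNA, cm³/g.  Calibrated once against published
# SLD / contrast-match-point values for partially and fully deuterated RNA;
# see docs/methods.md for the calibration.  Configurable per molecule.
VBAR_RNA = 0.548

# Default completeness of labile (N/O-bound) hydrogen exchange with solvent.
# Structured RNA protects a fraction of imino/amino protons, so full
# equilibration is not reached on experimental timescales; the default is
# part of the same calibration as VBAR_RNA.
F_EXCH_DEFAULT = 0.85

# Ratio of the incoherent scattering cross sections of 1H and 2H; drives the
# flat-background model of synthetic SANS profiles.
INCOHERENT_H_OVER_D = 40.0

# Displaced-solvent volumes for heavy atoms, Å³ (Fraser-style dummy atoms).
# The hydrogen entry is added per riding hydrogen.
DISPLACED_VOLUME = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "P": 5.73,
}

# Porod molecular-weight defaults: integration cutoff (Å⁻¹) and RNA
# mass density (kDa/Å³).
POROD_Q_CUTOFF = 0.15
POROD_DENSITY_KDA_A3 = 0.00054


def water_sld(heavy: bool) -> float:
    """SLD of pure H₂O or D₂O at 20 °C, in 1e-6 Å⁻²."""
    iso = "D" if heavy else "H"
    b_sum = 2.0 * COHERENT_B[iso] + COHERENT_B["O"]  # fm
    mass = 2.0 * ATOMIC_MASS[iso] + ATOMIC_MASS["O"]
    density = DENSITY_D2O if heavy else DENSITY_H2O
    # molecules per Å³ times fm, converted to 1e-6 Å⁻²
    n_per_a3 = density * AVOGADRO / mass * 1e-24
    return b_sum * n_per_a3 * 1e-5 * 1e6


SLD_H2O = water_sld(heavy=False)  # ≈ -0.56
SLD_D2O = water_sld(heavy=True)   # ≈ +6.36
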