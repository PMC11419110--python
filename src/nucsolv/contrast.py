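"""Neutron scattering length densities, contrast curves and match points.

The molecule SLD model is affine in both the solvent D₂O volume fraction x
(through labile-H exchange) and the non-exchangeable deuteration fraction d:

    ρ_mol(d, x) = [ Σb_heavy + N_nx·((1−d)·b_H + d·b_D)
                  + N_x·((1−f·x)·b_H + f·x·b_D) ] / V

with V = MW_protiated · v̄ / N_A held fixed under deuteration (isotope
substitution changes mass, not excluded volume).  The solvent SLD is the
volume-fraction mix of H₂O and D₂O.  Because both sides are affine in x, the
contrast match point x* solves a linear equation in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import AtomInventory
from .constants import (
    AVOGADRO,
    COHERENT_B,
    F_EXCH_DEFAULT,
    SLD_D2O,
    SLD_H2O,
    VBAR_RNA,
)

__all__ = [
    "SolventSpec",
    "LabeledMolecule",
    "ContrastCurve",
    "solvent_sld",
    "molecule_sld",
    "match_point",
    "required_deuteration",
    "contrast_curve",
]


@dataclass(frozen=True)
class SolventSpec:
    """An H₂O:D₂O mixture characterised by its D₂O volume fraction x."""

    x: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("D2O volume fraction x must lie in [0, 1]")


@dataclass(frozen=True)
class LabeledMolecule:
    """An RNA with a deuteration state.

    d       fraction of non-exchangeable (C-bound) H replaced by ²H
    f_exch  completeness of labile-H equilibration with the solvent
    v_bar   partial specific volume, cm³/g
    """

    inventory: AtomInventory
    d: float = 0.0
    f_exch: float = F_EXCH_DEFAULT
    v_bar: float = VBAR_RNA

    def __post_init__(self):
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")
        if not 0.0 <= self.f_exch <= 1.0:
            raise ValueError("f_exch must lie in [0, 1]")
        if self.v_bar <= 0:
            raise ValueError("v_bar must be positive")

    @property
    def volume_a3(self) -> float:
        """Excluded volume in Å³, fixed at the protiated mass."""
        return self.inventory.mass_protiated * 1000.0 * self.v_bar / AVOGADRO * 1e24


def solvent_sld(s: SolventSpec | float) -> float:
    """SLD of an H₂O:D₂O mixture in 1e-6 Å⁻² (ideal volume mixing)."""
    x = s.x if isinstance(s, SolventSpec) else SolventSpec(float(s)).x
    return (1.0 - x) * SLD_H2O + x * SLD_D2O


def _b_sum_fm(m: LabeledMolecule, x: float) -> float:
    inv = m.inventory
    b = COHERENT_B
    heavy = inv.n_C * b["C"] + inv.n_N * b["N"] + inv.n_O * b["O"] + inv.n_P * b["P"]
    nonexch = inv.n_H_nonexch * ((1.0 - m.d) * b["H"] + m.d * b["D"])
    p_d = m.f_exch * x  # probability a labile site carries ²H
    exch = inv.n_H_exch * ((1.0 - p_d) * b["H"] + p_d * b["D"])
    return heavy + nonexch + exch


def molecule_sld(m: LabeledMolecule, s: SolventSpec | float) -> float:
    """Molecule SLD in 1e-6 Å⁻² at solvent composition ``s``."""
    x = s.x if isinstance(s, SolventSpec) else SolventSpec(float(s)).x
    return _b_sum_fm(m, x) * 1e-5 / m.volume_a3 * 1e6


def match_point(m: LabeledMolecule) -> float | None:
    """Contrast match point x* in [0, 1], or None when unreachable.

    Both ρ_mol(x) and ρ_solv(x) are affine, so the crossing is solved exactly.
    Perdeuterated RNA exceeds the SLD of pure D₂O and returns None.
    """
    r0, r1 = molecule_sld(m, 0.0), molecule_sld(m, 1.0)
    s0, s1 = SLD_H2O, SLD_D2O
    denom = (s1 - s0) - (r1 - r0)
    if abs(denom) < 1e-12:
        if abs(r0 - s0) < 1e-12:
            raise ValueError("molecule and solvent SLDs coincide everywhere")
        return None
    x_star = (r0 - s0) / denom
    if not 0.0 <= x_star <= 1.0:
        return None
    return x_star


def required_deuteration(
    inv: AtomInventory,
    target_x: float,
    f_exch: float = F_EXCH_DEFAULT,
    v_bar: float = VBAR_RNA,
) -> float | None:
    """Non-exchangeable ²H fraction d that places the match point at target_x.

    ρ_mol(d, x) is affine in d at fixed x, so d is solved in closed form.
    Returns None when no d in [0, 1] achieves the target.
    """
    if not 0.0 <= target_x <= 1.0:
        raise ValueError("target_x must lie in [0, 1]")
    b = COHERENT_B
    m0 = LabeledMolecule(inv, d=0.0, f_exch=f_exch, v_bar=v_bar)
    rho0 = molecule_sld(m0, target_x)
    slope_d = inv.n_H_nonexch * (b["D"] - b["H"]) * 1e-5 / m0.volume_a3 * 1e6
    rho_solv = solvent_sld(target_x)
    if slope_d == 0.0:
        return 0.0 if abs(rho0 - rho_solv) < 1e-12 else None
    d = (rho_solv - rho0) / slope_d
    if -1e-12 <= d <= 1.0 + 1e-12:
        return float(min(max(d, 0.0), 1.0))
    return None


@dataclass(frozen=True)
class ContrastCurve:
    """Tabulated molecule/solvent SLDs and contrast over a grid of x."""

    x: np.ndarray
    rho_mol: np.ndarray
    rho_solv: np.ndarray
    delta_rho: np.ndarray
    match_point: float | None = None


def contrast_curve(m: LabeledMolecule, x_grid) -> ContrastCurve:
    """Tabulate ρ_mol, ρ_solv and Δρ on a grid of D₂O fractions."""
    x = np.asarray(x_grid, dtype=float)
    if x.size < 2:
        raise ValueError("grid needs at least two points")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("grid must lie within [0, 1]")
    rho_m = np.array([molecule_sld(m, xi) for xi in x])
    rho_s = np.array([solvent_sld(xi) for xi in x])
    return ContrastCurve(
        x=x,
        rho_mol=rho_m,
        rho_solv=rho_s,
        delta_rho=rho_m - rho_s,
        match_point=match_point(m),
    )
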