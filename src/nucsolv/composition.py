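"""Atomic composition of RNA chains with exchangeable/non-exchangeable H classes.

An RNA sequence is converted into an element inventory in which hydrogens are
split into two classes: *non-exchangeable* (carbon-bound; these are the sites
replaced by ²H during fractional deuteration of the nucleotide pool) and
*exchangeable* (N- or O-bound, including every 2′-OH; these equilibrate with
the solvent isotope composition).  Internal phosphodiesters are treated as
ionized, so no phosphate proton is counted and the molecular weight is that of
the polyanion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASS

__all__ = [
    "ResidueCounts",
    "TerminiSpec",
    "AtomInventory",
    "parse_sequence",
    "atom_inventory",
    "molecular_weight",
]

# Nucleoside formulas (free nucleoside, 5'-OH and 3'-OH present).
# H_nonexch: C-bound H (6 ribose CH + base CH); H_exch: N/O-bound H
# (2'-OH, 3'-OH, 5'-OH and base NH/NH2).
_NUCLEOSIDE = {
    "A": dict(C=10, N=5, O=4, H_nonexch=8, H_exch=5),
    "G": dict(C=10, N=5, O=5, H_nonexch=7, H_exch=6),
    "C": dict(C=9, N=3, O=5, H_nonexch=8, H_exch=5),
    "U": dict(C=9, N=2, O=6, H_nonexch=8, H_exch=4),
}

FIVE_PRIME_OPTIONS = ("hydroxyl", "monophosphate", "triphosphate")
THREE_PRIME_OPTIONS = ("hydroxyl", "phosphate")


@dataclass(frozen=True)
class ResidueCounts:
    """Counts of A/C/G/U residues in a single RNA chain."""

    counts: dict
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("a valid RNA needs at least one residue")
        if sum(self.counts.values()) != self.n:
            raise ValueError("residue counts do not sum to chain length")


@dataclass(frozen=True)
class TerminiSpec:
    """End-group chemistry of the chain.

    In vitro transcripts natively carry a 5'-triphosphate; the package default
    is 5'-OH / 3'-OH, the convention that reproduces sequence-calculated
    molecular weights as usually quoted.
    """

    five_prime: str = "hydroxyl"
    three_prime: str = "hydroxyl"

    def __post_init__(self):
        if self.five_prime not in FIVE_PRIME_OPTIONS:
            raise ValueError(f"five_prime must be one of {FIVE_PRIME_OPTIONS}")
        if self.three_prime not in THREE_PRIME_OPTIONS:
            raise ValueError(f"three_prime must be one of {THREE_PRIME_OPTIONS}")


@dataclass(frozen=True)
class AtomInventory:
    """Element counts of one RNA chain, hydrogens split by exchange class."""

    n_C: int
    n_N: int
    n_O: int
    n_P: int
    n_H_exch: int
    n_H_nonexch: int
    mass_protiated: float  # kDa
    n_residues: int = 0

    def __post_init__(self):
        for name in ("n_C", "n_N", "n_O", "n_P", "n_H_exch", "n_H_nonexch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def parse_sequence(text: str) -> ResidueCounts:
    """Parse a raw sequence string or single-record FASTA into residue counts.

    T is silently mapped to U (with a warning); any other character outside
    the A/C/G/U alphabet raises, naming its 1-based position.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    body = "".join(ln for ln in lines if ln and not ln.startswith((">", ";")))
    seq = "".join(body.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    if "T" in seq:
        warnings.warn("T residues mapped to U (DNA-style input)", stacklevel=2)
        seq = seq.replace("T", "U")
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    for pos, ch in enumerate(seq, start=1):
        if ch not in counts:
            raise ValueError(f"unknown residue {ch!r} at position {pos}")
        counts[ch] += 1
    return ResidueCounts(counts=counts, n=len(seq))


def atom_inventory(rc: ResidueCounts, termini: TerminiSpec | None = None) -> AtomInventory:
    """Assemble the element inventory of a linear chain.

    The chain is built as Σ nucleosides, with each of the (n−1) internal
    ionized phosphodiester linkages contributing +P +2O and consuming the two
    bridging hydroxyl protons (both exchangeable).  Terminal phosphates
    replace the corresponding terminal hydroxyl proton.
    """
    termini = termini or TerminiSpec()
    tot = dict(C=0, N=0, O=0, P=0, H_nonexch=0, H_exch=0)
    for res, k in rc.counts.items():
        for key, val in _NUCLEOSIDE[res].items():
            tot[key] += k * val
    n = rc.n
    tot["P"] += n - 1
    tot["O"] += 2 * (n - 1)
    tot["H_exch"] -= 2 * (n - 1)

    if termini.five_prime == "monophosphate":
        tot["P"] += 1
        tot["O"] += 3
        tot["H_exch"] -= 1
    elif termini.five_prime == "triphosphate":
        tot["P"] += 3
        tot["O"] += 9
        tot["H_exch"] -= 1
    if termini.three_prime == "phosphate":
        tot["P"] += 1
        tot["O"] += 3
        tot["H_exch"] -= 1

    inv = AtomInventory(
        n_C=tot["C"],
        n_N=tot["N"],
        n_O=tot["O"],
        n_P=tot["P"],
        n_H_exch=tot["H_exch"],
        n_H_nonexch=tot["H_nonexch"],
        mass_protiated=0.0,
        n_residues=n,
    )
    mass = molecular_weight(inv, d=0.0)
    return AtomInventory(
        n_C=inv.n_C,
        n_N=inv.n_N,
        n_O=inv.n_O,
        n_P=inv.n_P,
        n_H_exch=inv.n_H_exch,
        n_H_nonexch=inv.n_H_nonexch,
        mass_protiated=mass,
        n_residues=n,
    )


def molecular_weight(inv: AtomInventory, d: float = 0.0) -> float:
    """Sequence molecular weight in kDa.

    ``d`` is the ²H fraction of the non-exchangeable hydrogens; exchangeable
    hydrogens are counted as ¹H (the convention for the quoted protiated MW).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("deuteration fraction d must lie in [0, 1]")
    m = ATOMIC_MASS
    m_h_eff = (1.0 - d) * m["H"] + d * m["D"]
    mass = (
        inv.n_C * m["C"]
        + inv.n_N * m["N"]
        + inv.n_O * m["O"]
        + inv.n_P * m["P"]
        + inv.n_H_nonexch * m_h_eff
        + inv.n_H_exch * m["H"]
    )
    return mass / 1000.0


def sequence_inventory(text: str, termini: TerminiSpec | None = None) -> AtomInventory:
    """Convenience: parse a sequence and build its inventory in one step."""
    return atom_inventory(parse_sequence(text), termini)
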