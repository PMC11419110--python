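"""Readers and writers: three-column .dat profiles and PDB coordinates.

.dat files are whitespace-delimited 2/3/4-column numeric tables (q, I[, σ
[, extra]]), with '#'-prefixed or non-numeric header/footer lines preserved
as metadata — the format SASBDB-style reduced data ships in.  q is in Å⁻¹
(a ``q_units="nm"`` import flag divides by 10 on read).

PDB models are read through gemmi; hydrogens are implicit — every heavy atom
carries its riding-H count from a per-residue template, split into
exchangeable and non-exchangeable classes, so protonated inputs are not
required.  Waters are skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .constants import DISPLACED_VOLUME, F_EXCH_DEFAULT
from .debye import AtomicModel
from .profiles import ScatteringProfile

__all__ = ["read_dat", "write_dat", "read_pdb"]

log = logging.getLogger("nucsolv")

# riding hydrogens per heavy atom: name -> (non-exchangeable, exchangeable)
_RIBOSE_H = {
    "C1'": (1, 0), "C2'": (1, 0), "C3'": (1, 0), "C4'": (1, 0), "C5'": (2, 0),
    "O2'": (0, 1),
}
_BASE_H = {
    "A": {"C2": (1, 0), "C8": (1, 0), "N6": (0, 2)},
    "G": {"C8": (1, 0), "N1": (0, 1), "N2": (0, 2)},
    "C": {"C5": (1, 0), "C6": (1, 0), "N4": (0, 2)},
    "U": {"C5": (1, 0), "C6": (1, 0), "N3": (0, 1)},
}
_RES_ALIASES = {"A": "A", "RA": "A", "ADE": "A", "G": "G", "RG": "G", "GUA": "G",
                "C": "C", "RC": "C", "CYT": "C", "U": "U", "RU": "U", "URA": "U"}
_WATER = {"HOH", "WAT", "DOD"}


def read_dat(path, q_units: str = "angstrom") -> ScatteringProfile:
    """Read a 2/3/4-column text profile; header lines land in metadata."""
    path = Path(path)
    header, rows = [], []
    ncol = None
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            header.append(s.lstrip("# "))
            continue
        parts = s.split()
        try:
            vals = [float(v) for v in parts[:4]]
        except ValueError:
            header.append(s)
            continue
        if len(vals) < 2:
            header.append(s)
            continue
        if ncol is None:
            ncol = min(len(vals), 4)
        rows.append(vals[:ncol] + [np.nan] * (ncol - len(vals)))
    if len(rows) < 3:
        raise ValueError(f"{path}: fewer than 3 numeric rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    if not np.array_equal(order, np.arange(len(arr))):
        log.warning("%s: q not ascending, rows sorted", path)
        arr = arr[order]
    q = arr[:, 0]
    if q_units == "nm":
        q = q / 10.0
    elif q_units != "angstrom":
        raise ValueError("q_units must be 'angstrom' or 'nm'")
    sigma = None
    if arr.shape[1] >= 3 and np.all(np.isfinite(arr[:, 2])) and np.all(arr[:, 2] > 0):
        sigma = arr[:, 2]
    meta = {"path": str(path)}
    if header:
        meta["header"] = header
    return ScatteringProfile(q=q, I=arr[:, 1], sigma=sigma, metadata=meta)


def write_dat(profile: ScatteringProfile, path) -> None:
    """Write q, I(, σ) as a three-column text file with a provenance header."""
    path = Path(path)
    lines = ["# nucsolv scattering profile"]
    for key, val in profile.metadata.items():
        if key == "header":
            continue
        lines.append(f"# {key}: {val}")
    lines.append("# q I" + (" sigma" if profile.sigma is not None else ""))
    for k in range(len(profile)):
        row = f"{profile.q[k]:.10e} {profile.I[k]:.10e}"
        if profile.sigma is not None:
            row += f" {profile.sigma[k]:.10e}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if el and el != "X":
        return el.upper()
    name = atom.name.strip()
    for ch in name:  # atom-name heuristic: first alphabetic character
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom {atom.name!r}")


def read_pdb(path, chains=None, chain_labels=None, f_exch: float = F_EXCH_DEFAULT) -> AtomicModel:
    """Read heavy atoms of an RNA PDB into an AtomicModel.

    ``chains`` optionally restricts to a subset of chain ids; ``chain_labels``
    maps chain id -> deuteration fraction d (default 0 = protiated).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords, b_heavy, hn, hx, vol, ch_ids, resids = [], [], [], [], [], [], []
    from .constants import COHERENT_B

    for model in st:
        for chain in model:
            if chains is not None and chain.name not in set(np.atleast_1d(chains)):
                continue
            residues = [r for r in chain if r.name.strip() not in _WATER]
            for ri, res in enumerate(residues):
                rname = res.name.strip()
                if rname not in _RES_ALIASES:
                    raise ValueError(f"unknown residue {rname!r} in chain {chain.name}")
                code = _RES_ALIASES[rname]
                has_p = any(a.name.strip() == "P" for a in res)
                for atom in res:
                    el = _element_of(atom)
                    if el in ("H", "D"):
                        continue
                    name = atom.name.strip()
                    h = (0, 0)
                    if name in _RIBOSE_H:
                        h = _RIBOSE_H[name]
                    elif name in _BASE_H[code]:
                        h = _BASE_H[code][name]
                    elif name == "O5'" and ri == 0 and not has_p:
                        h = (0, 1)  # free 5'-OH
                    elif name == "O3'" and ri == len(residues) - 1:
                        h = (0, 1)  # free 3'-OH
                    n_h = h[0] + h[1]
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    b_heavy.append(COHERENT_B[el] if el in COHERENT_B else _b_lookup(el))
                    hn.append(h[0])
                    hx.append(h[1])
                    vol.append(DISPLACED_VOLUME.get(el, 15.0)
                               + n_h * DISPLACED_VOLUME["H"])
                    ch_ids.append(chain.name)
                    resids.append(res.seqid.num)
        break  # first model only
    if not coords:
        raise ValueError(f"{path}: no atoms left after filtering")
    ch_arr = np.array(ch_ids)
    labels = {c: 0.0 for c in np.unique(ch_arr)}
    if chain_labels:
        labels.update(chain_labels)
    return AtomicModel(
        coords=np.array(coords),
        b_heavy=np.array(b_heavy),
        n_h_nonexch=np.array(hn, dtype=float),
        n_h_exch=np.array(hx, dtype=float),
        volume=np.array(vol),
        chain=ch_arr,
        resid=np.array(resids),
        chain_labels=labels,
        f_exch=f_exch,
    )


def _b_lookup(el: str) -> float:
    raise ValueError(f"unknown element {el!r}: no scattering length on file")
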