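"""Shared fixtures: analytic profiles and small text-based coordinate files."""

import numpy as np
import pytest

import nucsolv as nv

SPHERE_R = 20.0
RG_SPHERE = np.sqrt(3.0 / 5.0) * SPHERE_R  # 15.4919...


@pytest.fixture(scope="session")
def sphere_profile_fine():
    """Noiseless analytic sphere profile, R = 20 Å, dense low-q grid."""
    q = np.linspace(0.004, 0.35, 320)
    return nv.sphere_profile(SPHERE_R, q, I0=1000.0, rel_sigma=1e-6)


@pytest.fixture(scope="session")
def gaussian_profile():
    """Exact Guinier curve: I = 100·exp(−q²·15²/3), σ = 1."""
    q = np.linspace(0.001, 0.4, 400)
    I = 100.0 * np.exp(-(q**2) * 15.0**2 / 3.0)
    return nv.ScatteringProfile(q=q, I=I, sigma=np.ones_like(q))


@pytest.fixture(scope="session")
def helix40_profile():
    """Noiseless profile of a long (40 bp) coarse helix — a rod-like fixture."""
    model = nv.generate_shape(nv.SynthSpec("helix", {"n_bp": 40}, bead="nt"))
    q = np.linspace(0.008, 0.45, 150)
    prof = nv.debye_intensity(model, q, solvent=None)
    return nv.ScatteringProfile(
        q=q, I=prof.I, sigma=np.full_like(q, prof.I.max() * 1e-4)
    )


PDB_FIXTURE = """\
ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  C1'   G A   1       3.000   0.000   0.000  1.00  0.00           C
ATOM      3  N1    G A   1       0.000   4.000   0.000  1.00  0.00           N
ATOM      4  O2'   G A   1       0.000   0.000   5.000  1.00  0.00           O
ATOM      5  C1'   U B   2      10.000   0.000   0.000  1.00  0.00           C
ATOM      6  O4    U B   2      10.000   3.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(PDB_FIXTURE)
    return path


@pytest.fixture()
def pdb_file_no_element(tmp_path):
    """Same model with the element columns blanked (name-based inference)."""
    lines = []
    for line in PDB_FIXTURE.splitlines():
        if line.startswith("ATOM"):
            line = line[:76] + "  "
        lines.append(line)
    path = tmp_path / "mini_noel.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
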