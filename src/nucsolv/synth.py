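"""Synthetic coordinate fixtures and noisy SANS-like profiles.

The shapes emulate the geometries seen in solution studies of small RNAs:
compact quasi-spherical hairpins, elongated rods, coarse-grained two-strand
A-form helices (one bead per nucleotide, rise 2.81 Å/bp, backbone radius
9 Å ≈ 20 Å cross-section), and two-hairpin kissing-style complexes joined
end-to-end.  The noise model reflects reduced (averaged) small-angle neutron
data: a flat incoherent background that grows with the solvent ¹H content
(¹H:²H incoherent weight ratio 40) and heteroscedastic Gaussian noise whose
width shrinks as 1/√exposure.  All randomness is driven by a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import _NUCLEOSIDE
from .constants import (
    ATOMIC_MASS,
    AVOGADRO,
    COHERENT_B,
    F_EXCH_DEFAULT,
    INCOHERENT_H_OVER_D,
    VBAR_RNA,
)
from .debye import AtomicModel, debye_intensity, merge_models
from .profiles import ScatteringProfile

__all__ = [
    "SynthSpec",
    "generate_shape",
    "synth_profile",
    "nt_bead_parameters",
    "sphere_form_factor",
    "sphere_profile",
]

SHAPES = ("sphere", "rod", "helix", "hairpin", "two_hairpin_complex")

# A-form-like coarse helix defaults
HELIX_RISE = 2.81       # Å per bp
HELIX_RADIUS = 9.0      # Å, backbone bead radius (≈ 20 Å cross-section)
HELIX_TWIST = 32.7      # degrees per bp
HELIX_STRAND_OFFSET = 165.0  # degrees between the two strands


def nt_bead_parameters() -> dict:
    """Average-nucleotide bead: scattering lengths, H classes, volume.

    Built from the equimolar internal-residue composition (nucleoside + one
    ionized phosphodiester linkage) so that bead models stay consistent with
    the sequence-level contrast calculations.
    """
    el = dict(C=0.0, N=0.0, O=0.0, P=0.0, Hn=0.0, Hx=0.0)
    for res in "ACGU":
        t = _NUCLEOSIDE[res]
        el["C"] += t["C"] / 4.0
        el["N"] += t["N"] / 4.0
        el["O"] += t["O"] / 4.0
        el["Hn"] += t["H_nonexch"] / 4.0
        el["Hx"] += t["H_exch"] / 4.0
    el["P"] += 1.0
    el["O"] += 2.0
    el["Hx"] -= 2.0
    b = COHERENT_B
    b_heavy = el["C"] * b["C"] + el["N"] * b["N"] + el["O"] * b["O"] + el["P"] * b["P"]
    m = ATOMIC_MASS
    mass = (
        el["C"] * m["C"] + el["N"] * m["N"] + el["O"] * m["O"] + el["P"] * m["P"]
        + (el["Hn"] + el["Hx"]) * m["H"]
    )
    volume = mass * VBAR_RNA / AVOGADRO * 1e24
    return {
        "b_heavy": b_heavy,
        "n_h_nonexch": el["Hn"],
        "n_h_exch": el["Hx"],
        "volume": volume,
        "mass": mass,
    }


def sphere_form_factor(q, R: float) -> np.ndarray:
    """Normalized form factor of a homogeneous sphere, [3(sin u − u cos u)/u³]²."""
    u = np.asarray(q, dtype=float) * R
    out = np.ones_like(u)
    nz = u > 0
    out[nz] = (3.0 * (np.sin(u[nz]) - u[nz] * np.cos(u[nz])) / u[nz] ** 3) ** 2
    return out


def sphere_profile(R: float, q, I0: float = 1000.0, rel_sigma: float = 1e-6) -> ScatteringProfile:
    """Noiseless analytic sphere profile (σ is a nominal uniform uncertainty)."""
    q = np.asarray(q, dtype=float)
    I = I0 * sphere_form_factor(q, R)
    return ScatteringProfile(
        q=q, I=I, sigma=np.full_like(q, I0 * rel_sigma),
        metadata={"kind": "analytic_sphere", "R": R},
    )


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of a synthetic fixture."""

    shape: str
    geometry: dict = field(default_factory=dict)
    n: int = 3000
    seed: int | None = None
    bead: str = "point"
    chain: str = "A"
    label_d: float = 0.0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")


def _bead_arrays(n: int, bead: str):
    if bead == "point":
        return (np.ones(n), np.zeros(n), np.zeros(n), np.zeros(n))
    if bead == "nt":
        p = nt_bead_parameters()
        return (
            np.full(n, p["b_heavy"]),
            np.full(n, p["n_h_nonexch"]),
            np.full(n, p["n_h_exch"]),
            np.full(n, p["volume"]),
        )
    raise ValueError(f"unknown bead class {bead!r}")


def _model_from_coords(coords, spec_like) -> AtomicModel:
    n = len(coords)
    b, hn, hx, v = _bead_arrays(n, spec_like.bead)
    return AtomicModel(
        coords=coords,
        b_heavy=b,
        n_h_nonexch=hn,
        n_h_exch=hx,
        volume=v,
        chain=np.full(n, spec_like.chain),
        resid=np.arange(1, n + 1),
        chain_labels={spec_like.chain: spec_like.label_d},
    )


def _sphere_coords(spec: SynthSpec) -> np.ndarray:
    g = spec.geometry
    R = float(g.get("R", 20.0))
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    if g.get("method", "random") == "lattice":
        # symmetric cubic lattice filling the sphere; spacing set by n
        a = (4.0 / 3.0 * np.pi * R**3 / spec.n) ** (1.0 / 3.0)
        k = int(np.ceil(R / a))
        ax = (np.arange(-k, k + 1) + 0.5) * a
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= R**2]
        # boundary voxelization biases the effective radius by ~0.1%; rescale
        # so the coordinate Rg matches the continuum sphere exactly
        rg = np.sqrt(np.mean(np.sum(pts**2, axis=1)))
        return pts * (np.sqrt(3.0 / 5.0) * R / rg)
    rng = np.random.default_rng(spec.seed)
    r = R * rng.random(spec.n) ** (1.0 / 3.0)
    v = rng.normal(size=(spec.n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return r[:, None] * v


def _rod_coords(spec: SynthSpec) -> np.ndarray:
    g = spec.geometry
    L = float(g.get("length", 100.0))
    R = float(g.get("radius", 10.0))
    if L <= 0 or R <= 0:
        raise ValueError("rod length and radius must be positive")
    rng = np.random.default_rng(spec.seed)
    z = rng.uniform(-L / 2, L / 2, spec.n)
    rr = R * np.sqrt(rng.random(spec.n))
    phi = rng.uniform(0, 2 * np.pi, spec.n)
    return np.column_stack([rr * np.cos(phi), rr * np.sin(phi), z])


def _helix_coords(n_bp, rise, radius, twist_deg, offset_deg, z0=0.0):
    k = np.arange(n_bp)
    th1 = np.deg2rad(twist_deg) * k
    th2 = th1 + np.deg2rad(offset_deg)
    z = z0 + rise * k
    s1 = np.column_stack([radius * np.cos(th1), radius * np.sin(th1), z])
    s2 = np.column_stack([radius * np.cos(th2), radius * np.sin(th2), z])
    return np.vstack([s1, s2])


def _loop_cap(n_bp, rise, radius, twist_deg, offset_deg, z0=0.0, n_loop=5):
    """Arc of beads bridging the two strand ends above the stem top."""
    th_top1 = np.deg2rad(twist_deg) * (n_bp - 1)
    th_top2 = th_top1 + np.deg2rad(offset_deg)
    z_top = z0 + rise * (n_bp - 1)
    t = np.linspace(0, 1, n_loop + 2)[1:-1]
    th = th_top1 + t * (th_top2 - th_top1)
    lift = z_top + radius * 0.6 * np.sin(np.pi * t)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th), lift])


def _hairpin_coords(spec: SynthSpec, z0=0.0) -> np.ndarray:
    g = spec.geometry
    n_bp = int(g.get("n_bp", 12))
    if n_bp < 2:
        raise ValueError("hairpin needs at least 2 bp")
    rise = float(g.get("rise", HELIX_RISE))
    radius = float(g.get("diameter", 2 * HELIX_RADIUS)) / 2.0
    twist = float(g.get("twist", HELIX_TWIST))
    off = float(g.get("strand_offset", HELIX_STRAND_OFFSET))
    stem = _helix_coords(n_bp, rise, radius, twist, off, z0=z0)
    loop = _loop_cap(n_bp, rise, radius, twist, off, z0=z0,
                     n_loop=int(g.get("n_loop", 5)))
    return np.vstack([stem, loop])


def generate_shape(spec: SynthSpec) -> AtomicModel:
    """Deterministic (given the seed) particle cloud for the requested shape."""
    if spec.shape == "sphere":
        return _model_from_coords(_sphere_coords(spec), spec)
    if spec.shape == "rod":
        return _model_from_coords(_rod_coords(spec), spec)
    if spec.shape == "helix":
        g = spec.geometry
        n_bp = int(g.get("n_bp", 16))
        if n_bp < 2:
            raise ValueError("helix needs at least 2 bp")
        coords = _helix_coords(
            n_bp,
            float(g.get("rise", HELIX_RISE)),
            float(g.get("diameter", 2 * HELIX_RADIUS)) / 2.0,
            float(g.get("twist", HELIX_TWIST)),
            float(g.get("strand_offset", HELIX_STRAND_OFFSET)),
        )
        return _model_from_coords(coords, spec)
    if spec.shape == "hairpin":
        return _model_from_coords(_hairpin_coords(spec), spec)
    if spec.shape == "two_hairpin_complex":
        g = spec.geometry
        ga = dict(g.get("hairpin_a", {}))
        gb = dict(g.get("hairpin_b", {}))
        bend = np.deg2rad(float(g.get("bend", 0.0)))
        gap = float(g.get("gap", HELIX_RISE))
        spec_a = SynthSpec("hairpin", ga, bead=spec.bead, chain="A",
                           label_d=float(g.get("d_a", 0.0)))
        spec_b = SynthSpec("hairpin", gb, bead=spec.bead, chain="B",
                           label_d=float(g.get("d_b", 0.0)))
        # hairpin A points up (+z), its open end at z=0; B continues downwards
        a = _model_from_coords(_hairpin_coords(spec_a), spec_a)
        cb = _hairpin_coords(spec_b)
        # flip B so its open end faces A's open end, then bend and shift
        cb = cb * np.array([1.0, -1.0, -1.0])
        rot = np.array([
            [np.cos(bend), 0.0, np.sin(bend)],
            [0.0, 1.0, 0.0],
            [-np.sin(bend), 0.0, np.cos(bend)],
        ])
        cb = cb @ rot.T
        cb[:, 2] -= gap
        b = _model_from_coords(cb, spec_b)
        return merge_models(a, b)
    raise ValueError(f"unknown shape {spec.shape!r}")


def synth_profile(
    model: AtomicModel,
    q,
    seed: int,
    solvent_x: float | None = None,
    exposure: float = 1e4,
    bg_scale: float = 0.002,
    method: str = "auto",
) -> ScatteringProfile:
    """Noisy SANS-like profile of a model.

    I = Debye(model) + flat incoherent background.  The background weight is
    ((1−x)·40 + x)/40 — pure H₂O is 40× worse than pure D₂O — scaled by
    ``bg_scale``·I(0).  Gaussian noise has σ = √((I+bg)·I(0)/exposure), so
    quadrupling the exposure halves every error bar.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    clean = debye_intensity(model, q, solvent=solvent_x, method=method).I
    i0 = float(np.abs(clean).max())
    if solvent_x is None:
        bg = 0.0
    else:
        h_weight = ((1.0 - solvent_x) * INCOHERENT_H_OVER_D + solvent_x) / INCOHERENT_H_OVER_D
        bg = bg_scale * i0 * h_weight
    expected = clean + bg
    sigma = np.sqrt(np.maximum(expected + bg, 1e-12 * i0) * i0 / exposure)
    noisy = expected + rng.normal(0.0, sigma)
    meta = {
        "kind": "synthetic",
        "seed": seed,
        "solvent_x": solvent_x,
        "exposure": exposure,
        "background": bg,
        "n_particles": len(model),
    }
    return ScatteringProfile(q=q, I=noisy, sigma=sigma, metadata=meta)
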