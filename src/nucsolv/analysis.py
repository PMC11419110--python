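"""Primary solution-scattering analysis: Guinier, Kratky, Porod MW, rebinning.

The Guinier approximation ln I(q) ≈ ln I(0) − q²Rg²/3 holds to qRg ≈ 1.3 for
globular particles and ≈ 1.0 for elongated ones; the automatic window search
enforces the chosen ceiling self-consistently.  The dimensionless Kratky
transform (qRg)²I/I(0) vs qRg peaks at (√3, 3/e) for an ideal compact
scatterer.  The Porod route to molecular weight is concentration-free:
Vp = 2π² I(0)/Q with Q the Porod invariant integrated to a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import POROD_DENSITY_KDA_A3, POROD_Q_CUTOFF
from .profiles import ScatteringProfile

__all__ = [
    "GuinierResult",
    "KratkyCurve",
    "PorodResult",
    "guinier_fit",
    "dimensionless_kratky",
    "porod_mw",
    "log_rebin",
]


@dataclass(frozen=True)
class GuinierResult:
    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    q_min: float
    q_max: float
    qRg_max: float
    r_squared: float
    n_points: int


def _wls_line(x, y, w):
    """Weighted least squares y = a + b·x; returns a, b, var_a, var_b, r²."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    var_b = s2 / sxx
    var_a = s2 * (1.0 / W + xm**2 / sxx)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    return a, b, var_a, var_b, r2


def _fit_window(q, ln_i, w):
    a, b, va, vb, r2 = _wls_line(q**2, ln_i, w)
    if b >= 0:
        return None
    rg = np.sqrt(-3.0 * b)
    rg_err = 1.5 * np.sqrt(vb) / rg
    i0 = np.exp(a)
    i0_err = i0 * np.sqrt(va)
    return rg, rg_err, i0, i0_err, r2


def guinier_fit(
    p: ScatteringProfile,
    qrg_ceiling: float = 1.3,
    min_points: int = 8,
    r2_min: float = 0.99,
    window: tuple | None = None,
) -> GuinierResult:
    """Weighted Guinier fit of ln I vs q² with automatic window selection.

    Non-positive intensities are excluded from candidacy.  Starting from each
    of the first few usable points, the window end is grown/shrunk until
    q_max·Rg settles at or below the ceiling (self-consistent iteration); among
    windows reaching r² ≥ r2_min the longest is kept.  ``window=(q_lo, q_hi)``
    bypasses the search.
    """
    q, I = p.q, p.I
    sigma = p.sigma if p.sigma is not None else np.ones_like(q)
    ok = I > 0
    if window is not None:
        ok &= (q >= window[0]) & (q <= window[1])
        if ok.sum() < 3:
            raise ValueError("fixed Guinier window contains too few positive points")
        idx = np.flatnonzero(ok)
        qq, ii, ss = q[idx], I[idx], sigma[idx]
        res = _fit_window(qq, np.log(ii), (ii / ss) ** 2)
        if res is None:
            raise ValueError("no Guinier region: non-negative slope in fixed window")
        rg, rg_err, i0, i0_err, r2 = res
        return GuinierResult(rg, rg_err, i0, i0_err, qq[0], qq[-1],
                             qq[-1] * rg, r2, len(qq))

    idx_ok = np.flatnonzero(ok)
    if idx_ok.size < min_points:
        raise ValueError("no Guinier region: too few positive intensities")
    qv, iv, sv = q[idx_ok], I[idx_ok], sigma[idx_ok]
    lnv = np.log(iv)
    wv = (iv / sv) ** 2

    best = None  # (n_points, -start) maximised subject to r² >= r2_min
    fallback = None  # best r² otherwise
    n = len(qv)
    min_pts = min(min_points, max(n // 2, 5))
    for start in range(0, min(10, n - min_pts)):
        end = n  # exclusive
        for _ in range(30):  # self-consistency loop on qRg ceiling
            res = _fit_window(qv[start:end], lnv[start:end], wv[start:end])
            if res is None:
                end -= 1
                if end - start < min_pts:
                    break
                continue
            rg = res[0]
            new_end = int(np.searchsorted(qv, qrg_ceiling / rg, side="right"))
            new_end = max(min(new_end, n), start + min_pts)
            if new_end == end:
                break
            end = new_end
        else:
            res = None
        if res is None or end - start < min_pts:
            continue
        rg, rg_err, i0, i0_err, r2 = res
        if qv[end - 1] * rg > qrg_ceiling * 1.05:
            continue
        cand = (end - start, -start, (start, end, res))
        if r2 >= r2_min:
            if best is None or cand[:2] > best[:2]:
                best = cand
        elif fallback is None or r2 > fallback[0]:
            fallback = (r2, (start, end, res))

    if best is not None:
        start, end, res = best[2]
    elif fallback is not None:
        start, end, res = fallback[1]
    else:
        raise ValueError("no Guinier region found")
    rg, rg_err, i0, i0_err, r2 = res
    return GuinierResult(
        Rg=rg, Rg_err=rg_err, I0=i0, I0_err=i0_err,
        q_min=qv[start], q_max=qv[end - 1],
        qRg_max=qv[end - 1] * rg, r_squared=r2, n_points=end - start,
    )


@dataclass(frozen=True)
class KratkyCurve:
    """Dimensionless Kratky transform (qRg)²·I/I0 against qRg."""

    x: np.ndarray          # qRg
    y: np.ndarray          # (qRg)² I / I0
    sigma: np.ndarray | None
    peak_x: float
    peak_y: float


def dimensionless_kratky(p: ScatteringProfile, g: GuinierResult) -> KratkyCurve:
    """Transform a profile to dimensionless Kratky coordinates.

    The peak is located by a three-point parabolic refinement around the
    gridded maximum.
    """
    if g.I0 <= 0:
        raise ValueError("I0 must be positive")
    x = p.q * g.Rg
    y = x**2 * p.I / g.I0
    s = None if p.sigma is None else x**2 * p.sigma / g.I0
    k = int(np.argmax(y))
    if 0 < k < len(y) - 1:
        x3, y3 = x[k - 1 : k + 2], y[k - 1 : k + 2]
        denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
        a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
        b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0]) + x3[0] ** 2 * (y3[1] - y3[2])) / denom
        if a < 0:
            px = -b / (2 * a)
            c = y3[0] - a * x3[0] ** 2 - b * x3[0]
            py = a * px**2 + b * px + c
        else:
            px, py = x[k], y[k]
    else:
        px, py = x[k], y[k]
    return KratkyCurve(x=x, y=y, sigma=s, peak_x=float(px), peak_y=float(py))


@dataclass(frozen=True)
class PorodResult:
    Vp: float      # Å³
    MW: float      # kDa
    Q: float       # Porod invariant up to the cutoff
    q_cutoff: float


def porod_mw(
    p: ScatteringProfile,
    g: GuinierResult,
    q_cutoff: float = POROD_Q_CUTOFF,
    density: float = POROD_DENSITY_KDA_A3,
) -> PorodResult:
    """Porod-volume molecular weight.

    Q = ∫₀^cutoff q² I dq via the trapezoid rule; the gap between q = 0 and
    the first data point is filled with the Guinier model.  Negative
    intensities are retained in the linear-space integral.
    """
    if p.q[-1] < q_cutoff:
        raise ValueError(
            f"data end at q = {p.q[-1]:.4f} Å⁻¹, short of the cutoff "
            f"{q_cutoff} Å⁻¹; use q_cutoff <= {p.q[-1]:.4f}"
        )
    keep = p.q <= q_cutoff
    q, I = p.q[keep], p.I[keep]
    # Guinier extrapolation from 0 to the first measured point
    q_lo = np.linspace(0.0, q[0], 64)
    i_lo = g.I0 * np.exp(-(q_lo**2) * g.Rg**2 / 3.0)
    Q_lo = np.trapezoid(q_lo**2 * i_lo, q_lo)
    Q_data = np.trapezoid(q**2 * I, q)
    Q = Q_lo + Q_data
    vp = 2.0 * np.pi**2 * g.I0 / Q
    return PorodResult(Vp=float(vp), MW=float(vp * density), Q=float(Q), q_cutoff=q_cutoff)


def log_rebin(p: ScatteringProfile, points_per_decade: int) -> ScatteringProfile:
    """Rebin onto geometric q bins with the requested points per log decade.

    Intensities are combined by inverse-variance weighting (plain means when
    the profile carries no uncertainties); empty bins are dropped.
    """
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    pos = p.q > 0
    q, I = p.q[pos], p.I[pos]
    sigma = p.sigma[pos] if p.sigma is not None else None
    lo, hi = np.log10(q[0]), np.log10(q[-1])
    n_bins = max(1, int(np.ceil((hi - lo) * points_per_decade)))
    edges = np.logspace(lo, lo + n_bins / points_per_decade, n_bins + 1)
    edges[0] *= 1 - 1e-12
    edges[-1] = max(edges[-1], q[-1] * (1 + 1e-12))
    which = np.digitize(q, edges) - 1
    qs, Is, ss = [], [], []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        if sigma is not None:
            w = 1.0 / sigma[m] ** 2
            qs.append(np.sum(w * q[m]) / np.sum(w))
            Is.append(np.sum(w * I[m]) / np.sum(w))
            ss.append(np.sqrt(1.0 / np.sum(w)))
        else:
            qs.append(q[m].mean())
            Is.append(I[m].mean())
    meta = dict(p.metadata)
    meta["rebinned_points_per_decade"] = points_per_decade
    return ScatteringProfile(
        q=np.array(qs),
        I=np.array(Is),
        sigma=np.array(ss) if sigma is not None else None,
        metadata=meta,
    )
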