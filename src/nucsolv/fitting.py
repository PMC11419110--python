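"""χ² comparison of theoretical profiles against experimental data.

The theoretical curve is interpolated onto the experimental grid and an
optimal scale (and, optionally, a flat background — the residual incoherent
term in SANS) is found in closed form by weighted least squares.  The
reported χ² is reduced by N − p, with p the number of fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ScatteringProfile

__all__ = ["FitResult", "fit_scale", "rank_models"]


@dataclass(frozen=True)
class FitResult:
    scale: float
    background: float | None
    chi2: float
    n_points: int
    residuals: np.ndarray


def _interp_calc(calc: ScatteringProfile, q: np.ndarray) -> np.ndarray:
    if q[0] < calc.q[0] - 1e-12 or q[-1] > calc.q[-1] + 1e-12:
        raise ValueError(
            "experimental q range extends beyond the theoretical grid; "
            "no extrapolation is performed"
        )
    return np.interp(q, calc.q, calc.I)


def fit_scale(
    calc: ScatteringProfile,
    exp: ScatteringProfile,
    fit_background: bool = False,
) -> FitResult:
    """Optimal scaling of a theoretical curve onto experimental data.

    Minimises Σ[(c·I_calc + b − I_exp)/σ]² in closed form; b is fitted only
    when ``fit_background`` is set.  χ² is reduced by N − p.
    """
    sigma = exp.require_sigma()
    ic = _interp_calc(calc, exp.q)
    if np.allclose(ic, 0.0):
        raise ValueError("theoretical curve is identically zero")
    w = 1.0 / sigma**2
    if fit_background:
        X = np.column_stack([ic, np.ones_like(ic)])
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ exp.I)
        c, b = float(beta[0]), float(beta[1])
        model = c * ic + b
        p = 2
    else:
        c = float(np.sum(w * ic * exp.I) / np.sum(w * ic**2))
        b = None
        model = c * ic
        p = 1
    resid = (exp.I - model) / sigma
    dof = max(len(exp.q) - p, 1)
    return FitResult(
        scale=c,
        background=b,
        chi2=float(np.sum(resid**2) / dof),
        n_points=len(exp.q),
        residuals=resid,
    )


def rank_models(
    candidates,
    exp: ScatteringProfile,
    fit_background: bool = False,
    names=None,
) -> pd.DataFrame:
    """Rank candidate theoretical profiles against one dataset by χ².

    Returns a stable χ²-ascending table with a Δχ² column relative to the
    best model (the relative comparison that stays meaningful when large
    error bars deflate the absolute values).  Candidates that fail to fit are
    kept with a flag and excluded from the ranking order.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    names = names or [f"model_{i+1}" for i in range(len(candidates))]
    rows = []
    for name, calc in zip(names, candidates):
        try:
            fr = fit_scale(calc, exp, fit_background=fit_background)
            rows.append({"name": name, "chi2": fr.chi2, "scale": fr.scale,
                         "background": fr.background, "error": None})
        except ValueError as err:
            rows.append({"name": name, "chi2": np.inf, "scale": np.nan,
                         "background": None, "error": str(err)})
    table = pd.DataFrame(rows)
    table = table.sort_values("chi2", kind="stable").reset_index(drop=True)
    finite = np.isfinite(table["chi2"])
    best = table.loc[finite, "chi2"].min() if finite.any() else np.nan
    table["delta_chi2"] = table["chi2"] - best
    table["rank"] = np.arange(1, len(table) + 1)
    return table
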