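"""Langmuir adsorption isotherm fitting and adsorption-dose arithmetic.

The Langmuir model Gamma(c) = Gamma_max * K * c / (1 + K * c) describes
monolayer adsorption: Gamma_max is the monolayer capacity (mg of protein
per m^2 of surface) and K the affinity constant (L/g).  The surface dose
available for adsorption in an experiment is nanoparticle concentration x
volume x specific surface area (BET).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import IsothermData


def surface_dose(np_conc: float, volume: float, s_bet: float) -> float:
    """Total surface area (m^2) offered for adsorption.

    Parameters: nanoparticle concentration (g/L), sample volume (L) and
    specific surface area S_BET (m^2/g).  All must be positive.
    """
    if np_conc <= 0 or volume <= 0 or s_bet <= 0:
        raise ValueError("all inputs must be positive")
    return np_conc * volume * s_bet


def langmuir_gamma(c_eq, gamma_max: float, k_aff: float):
    """Langmuir adsorbed amount (mg/m^2) at equilibrium concentration c_eq (g/L)."""
    c_eq = np.asarray(c_eq, dtype=float)
    if np.any(c_eq < 0):
        raise ValueError("equilibrium concentration must be non-negative")
    out = gamma_max * k_aff * c_eq / (1.0 + k_aff * c_eq)
    return float(out) if out.ndim == 0 else out


@dataclass
class LangmuirFit:
    """Fitted Langmuir parameters with standard errors and residual norm."""

    gamma_max: float     # mg/m^2
    k_aff: float         # L/g
    gamma_max_stderr: float
    k_aff_stderr: float
    residual_norm: float
    converged: bool

    def predict(self, c_eq):
        return langmuir_gamma(c_eq, self.gamma_max, self.k_aff)


def _linearized_init(data: IsothermData) -> tuple[float, float]:
    # double-reciprocal: 1/gamma = 1/gamma_max + (1/(gamma_max*k)) * (1/c)
    mask = (data.c_eq > 0) & (data.gamma > 0)
    if mask.sum() >= 2:
        inv_c = 1.0 / data.c_eq[mask]
        inv_g = 1.0 / data.gamma[mask]
        slope, intercept = np.polyfit(inv_c, inv_g, 1)
        if intercept > 0 and slope > 0:
            return 1.0 / intercept, intercept / slope
    # fallback: plateau guess and half-saturation near the median concentration
    gmax = float(data.gamma.max()) or 1.0
    pos = data.c_eq[data.c_eq > 0]
    k = 1.0 / float(np.median(pos)) if len(pos) else 1.0
    return gmax, k


def fit_langmuir(data: IsothermData, init: tuple[float, float] | None = None) -> LangmuirFit:
    """Fit (Gamma_max, K) by unweighted nonlinear least squares.

    Initial values come from the linearized double-reciprocal regression
    unless given.  Requires >= 3 points with >= 2 distinct equilibrium
    concentrations and at least one nonzero adsorbed amount.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 isotherm points")
    if len(np.unique(data.c_eq)) < 2:
        raise ValueError("need at least 2 distinct equilibrium concentrations")
    if np.all(data.gamma == 0):
        raise ValueError("degenerate data: all adsorbed amounts are zero")

    p0 = init if init is not None else _linearized_init(data)
    try:
        popt, pcov = curve_fit(
            langmuir_gamma, data.c_eq, data.gamma, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
        converged = True
    except RuntimeError as err:
        raise RuntimeError(f"Langmuir fit did not converge: {err}") from err
    residuals = data.gamma - langmuir_gamma(data.c_eq, *popt)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return LangmuirFit(
        gamma_max=float(popt[0]), k_aff=float(popt[1]),
        gamma_max_stderr=float(stderr[0]), k_aff_stderr=float(stderr[1]),
        residual_norm=float(np.linalg.norm(residuals)), converged=converged,
    )
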