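"""Emergent growth laws, Monod kinetics, and mass-fraction/concentration units.

Whenever the steady-state amino-acid pool sits on the optimality plateau
(``K_gamma << a* << K_nu``) both efficiencies are pinned at their maxima and
the two empirical growth laws fall out of the flux constraints:

* nutrient modulation (vary ``nu0``):  phi_R = phiR_min + lambda / gamma0 —
  a line with positive slope 1/gamma0 and intercept phiR_min;
* translation modulation (scale ``gamma0``, e.g. sub-lethal ribosome-binding
  antibiotics):  phi_R = phiR_max - lambda / nu0 — negative slope -1/nu0,
  intercept phiR_max.

The sweeps here generate (lambda*, phi_R*) points from the *regulated*
system (fixed point of supply-driven activation), fit a line, and report the
implied efficiency — demonstrating that the laws emerge from the regulation
rather than from an explicit optimization.

When amino-acid supply is transport-limited, the transporter efficacy takes
a Michaelis form ``k_a = k_cat * a_ex / (K_M + a_ex)`` in the external
substrate concentration ``a_ex``.  Substituting into the supply flux and
eliminating phi_R through the protein-synthesis constraint yields a Monod
relation (derivation in docs/methods.md):

    lambda(a_ex) = lambda_inf * a_ex / (a_ex + K_M_app),
    lambda_inf   = gamma * nu_inf * (phiR_max - phiR_min) / (gamma + nu_inf),
    K_M_app      = K_M * gamma / (gamma + nu_inf),

so the apparent Michaelis constant inherits a growth-medium dependence
through the efficiencies.

Unit conversions follow the proportionality phi_i = sigma * c_i * N_aa with
sigma = 3.8e-7 per µM per residue (total protein mass tracks dry mass and
cell density is constant across conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError, GrowthParams
from .dynamics import ControlFunction, find_fixed_point, make_control_function
from .steady_state import optimize_allocation

__all__ = [
    "GrowthLawFit",
    "MonodParams",
    "SIGMA_PER_UM_PER_RESIDUE",
    "MEAN_RESIDUE_MASS_DA",
    "linear_fit",
    "fit_growth_law",
    "standard_control",
    "first_growth_law_sweep",
    "second_growth_law_sweep",
    "monod_params",
    "monod_growth_rate",
    "mass_fraction_from_concentration",
    "concentration_from_mass_fraction",
]

#: conversion factor from concentration (µM) to mass fraction, per residue
SIGMA_PER_UM_PER_RESIDUE = 3.8e-7
#: average molecular weight per amino-acid residue (Daltons); informational
MEAN_RESIDUE_MASS_DA = 110.0


@dataclass(frozen=True)
class GrowthLawFit:
    """Ordinary least-squares line through (lambda, phi_R) points.

    ``efficiency`` is the implied maximal efficiency: 1/slope for a nutrient
    sweep (recovers gamma0), -1/slope for a translation sweep (recovers nu0).
    """

    slope: float          # hours
    intercept: float      # proteome fraction
    r_squared: float
    efficiency: float     # 1/hour
    law: str              # "nutrient-sweep" | "translation-sweep"


@dataclass(frozen=True)
class MonodParams:
    """Transport-limited supply parameters and derived Monod constants.

    ``nu_inf`` is the nutritional efficiency at saturating external
    substrate (transporter ``k_cat`` with expression level folded in).
    """

    lambda_inf: float     # 1/h
    k_cat: float          # 1/h (saturating nutritional efficiency nu_inf)
    K_M: float            # external concentration units
    K_M_app: float        # external concentration units

    def __post_init__(self):
        for name in ("lambda_inf", "k_cat", "K_M", "K_M_app"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def linear_fit(x, y) -> tuple[float, float, float]:
    """OLS line fit returning (slope, intercept, R^2).

    Requires at least 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a line fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x values are all identical")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_growth_law(lam, phiR, law: str = "nutrient-sweep") -> GrowthLawFit:
    """Fit phi_R against lambda and report the implied efficiency."""
    slope, intercept, r2 = linear_fit(lam, phiR)
    if law == "nutrient-sweep":
        eff = 1.0 / slope
    elif law == "translation-sweep":
        eff = -1.0 / slope
    else:
        raise ValueError(f"unknown law tag {law!r}")
    return GrowthLawFit(slope=slope, intercept=intercept, r_squared=r2,
                        efficiency=eff, law=law)


def standard_control(p: GrowthParams, h: float = 2.0) -> ControlFunction:
    """A generic supply-driven-activation rule for sweeps.

    Hill activation from 0 up to ``phiR_max`` with half-point at the
    geometric mean of the two attenuation thresholds — it crosses the
    flux-balance curve for every admissible parameter set, with no tuning
    to any particular nutrient environment.
    """
    K_chi = float(np.sqrt(p.K_gamma * p.K_nu))
    return make_control_function(
        "hill", baseline=0.0, amplitude=p.phiR_max, K_chi=K_chi, h=h
    )


def _sweep(params_list, p_label, chi, use_optimizer):
    rows = []
    for label_value, p_i in params_list:
        if use_optimizer:
            rep = optimize_allocation(p_i)
            lam, phiR = rep.lambda_opt, rep.phiR_opt
        else:
            ss = find_fixed_point(chi if chi is not None else standard_control(p_i), p_i)
            lam, phiR = ss.lambda_star, ss.phiR_star
        rows.append({p_label: label_value, "lam": lam, "phiR": phiR})
    return pd.DataFrame(rows)


def first_growth_law_sweep(
    nu0_grid,
    p: GrowthParams,
    chi: ControlFunction | None = None,
    use_optimizer: bool = False,
) -> tuple[pd.DataFrame, GrowthLawFit]:
    """Nutrient-quality sweep: vary nu0, collect (lambda*, phi_R*), fit the first law.

    In the plateau limit the recovered slope is 1/gamma0 and the intercept
    phiR_min.  By default each point is the fixed point of the regulated
    system under a single generic control function; ``use_optimizer=True``
    substitutes the idealized growth-rate maximum instead.
    """
    nu0_grid = np.asarray(nu0_grid, dtype=float)
    if nu0_grid.size < 3:
        raise ValueError("nu0 grid needs at least 3 values")
    if np.any(nu0_grid <= 0):
        raise ValueError("nu0 values must be > 0")
    table = _sweep(
        [(nu0, p.replace(nu0=float(nu0))) for nu0 in nu0_grid],
        "nu0", chi, use_optimizer,
    )
    fit = fit_growth_law(table["lam"], table["phiR"], law="nutrient-sweep")
    return table, fit


def second_growth_law_sweep(
    gamma0_grid,
    p: GrowthParams,
    chi: ControlFunction | None = None,
    use_optimizer: bool = False,
) -> tuple[pd.DataFrame, GrowthLawFit]:
    """Translation-inhibition sweep: vary gamma0 at fixed nu0, fit the second law.

    Scaling gamma0 downward models sub-lethal doses of ribosome-targeting
    antibiotics (chloramphenicol-type), which reduce translational
    efficiency without significantly affecting nu.  Plateau-limit recovery:
    slope -1/nu0, intercept phiR_max.
    """
    gamma0_grid = np.asarray(gamma0_grid, dtype=float)
    if gamma0_grid.size < 3:
        raise ValueError("gamma0 grid needs at least 3 values")
    if np.any(gamma0_grid <= 0):
        raise ValueError("gamma0 values must be > 0")
    table = _sweep(
        [(g0, p.replace(gamma0=float(g0))) for g0 in gamma0_grid],
        "gamma0", chi, use_optimizer,
    )
    fit = fit_growth_law(table["lam"], table["phiR"], law="translation-sweep")
    return table, fit


def monod_params(p: GrowthParams, k_cat: float, K_M: float) -> MonodParams:
    """Derive the Monod constants for transport-limited supply.

    ``k_cat`` plays the role of the saturating nutritional efficiency
    nu_inf; the translational efficiency enters at its maximum gamma0
    (plateau conditions).
    """
    if k_cat <= 0 or K_M <= 0:
        raise ValueError("k_cat and K_M must be > 0")
    g = p.gamma0
    lambda_inf = g * k_cat * p.dphi / (g + k_cat)
    K_M_app = K_M * g / (g + k_cat)
    return MonodParams(lambda_inf=lambda_inf, k_cat=k_cat, K_M=K_M,
                       K_M_app=K_M_app)


def monod_growth_rate(a_ex, m: MonodParams):
    """Growth rate versus external substrate: lambda_inf * a_ex / (a_ex + K_M_app)."""
    a_ex = np.asarray(a_ex, dtype=float)
    if np.any(a_ex < 0):
        raise DomainError("external concentration a_ex must be >= 0")
    out = m.lambda_inf * a_ex / (a_ex + m.K_M_app)
    return out.item() if out.ndim == 0 else out


def mass_fraction_from_concentration(c_uM, N_aa: float):
    """Convert intracellular concentration (µM) to proteome mass fraction.

    phi = sigma * c * N_aa, with sigma = 3.8e-7 per µM per residue.
    """
    c_uM = np.asarray(c_uM, dtype=float)
    if np.any(c_uM < 0):
        raise DomainError("concentration must be >= 0")
    if not N_aa >= 1:
        raise ValueError("N_aa must be >= 1")
    out = SIGMA_PER_UM_PER_RESIDUE * c_uM * N_aa
    return out.item() if out.ndim == 0 else out


def concentration_from_mass_fraction(phi, N_aa: float):
    """Convert proteome mass fraction to intracellular concentration (µM)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise DomainError("mass fraction must be >= 0")
    if not N_aa >= 1:
        raise ValueError("N_aa must be >= 1")
    out = phi / (SIGMA_PER_UM_PER_RESIDUE * N_aa)
    return out.item() if out.ndim == 0 else out
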