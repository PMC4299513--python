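"""Flux-balance steady states, growth-rate optimization, and the optimality plateau.

For a fixed ribosomal fraction ``phi_R`` the amino-acid pool settles where
supply balances consumption,

    nu(a*) * (phiR_max - phi_R) = gamma(a*) * (phi_R - phiR_min),

which has a unique root in ``a`` because the left side is non-increasing and
the right side non-decreasing.  The induced growth rate
``lambda(phi_R) = gamma(a*(phi_R)) * (phi_R - phiR_min)`` vanishes at both
partition bounds and has a unique interior maximum.  When the attenuation
thresholds are well separated (``K_gamma << K_nu``) the maximum approaches
the closed-form bound obtained with both efficiencies at their maxima:

    lambda_hat = gamma0 * nu0 * (phiR_max - phiR_min) / (gamma0 + nu0),
    phiR_hat   = (gamma0 * phiR_min + nu0 * phiR_max) / (gamma0 + nu0),

and the flux-balance curve ``phi_R(a*)`` is nearly flat over a wide range of
pool sizes — the "optimality plateau" that makes growth-rate maximization
robust to the details of ribosome-synthesis regulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import (
    DomainError,
    GrowthParams,
    flux_residual,
    nutritional_efficiency,
    supply_flux,
    translation_flux,
    translational_efficiency,
)

__all__ = [
    "SteadyState",
    "OptimumReport",
    "DegenerateAllocationError",
    "SolverError",
    "solve_steady_amino_acid",
    "growth_rate_at",
    "phiR_balance",
    "closed_form_optimum",
    "optimize_allocation",
    "plateau_band",
]

#: relative tolerance on the amino-acid pool in root finding
DEFAULT_TOL = 1e-12


class DegenerateAllocationError(ValueError):
    """phi_R = phiR_min: consumption vanishes for every pool size, no finite
    flux-balance point exists."""


class SolverError(RuntimeError):
    """Root bracketing or refinement failed; message carries diagnostics."""


@dataclass(frozen=True)
class SteadyState:
    """A flux-balanced state of the model.

    ``supply`` and ``consumption`` are the two sides of the amino-acid
    balance (1/h); ``residual`` is their difference at the solution.
    ``eigenvalues``/``stable`` are filled by :func:`growthlaws.dynamics.stability`
    when the state is a fixed point of the regulated dynamics.
    """

    a_star: float
    phiR_star: float
    lambda_star: float
    supply: float
    consumption: float
    converged: bool = True
    residual: float = 0.0
    stable: bool | None = None
    eigenvalues: tuple[complex, complex] | None = field(default=None)


@dataclass(frozen=True)
class OptimumReport:
    """Result of maximizing growth rate over the ribosomal fraction."""

    phiR_opt: float
    lambda_opt: float
    a_opt: float
    phiR_hat: float       # closed-form allocation at maximal efficiencies
    lambda_hat: float     # closed-form upper bound on the growth rate
    plateau_a: tuple[float, float]      # pool-size interval within rel_tol of optimum
    plateau_phiR: tuple[float, float]   # corresponding phi_R band
    rel_tol: float = 0.10


def solve_steady_amino_acid(
    phiR: float, p: GrowthParams, tol: float = DEFAULT_TOL
) -> float:
    """Solve the flux balance for the steady-state pool ``a*`` at fixed phi_R.

    Unique by monotonicity of the residual.  The bracket starts at
    ``[K_gamma * 1e-6, K_nu * 1e6]`` and is expanded geometrically if the
    residual has not changed sign, since admissible pools span many decades.

    Raises
    ------
    DegenerateAllocationError
        If ``phiR == phiR_min`` (consumption identically zero).
    DomainError
        If ``phiR`` lies outside the partition bounds.
    SolverError
        If no sign change can be bracketed.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if phiR < p.phiR_min or phiR > p.phiR_max:
        raise DomainError(
            f"phiR={phiR} outside [{p.phiR_min}, {p.phiR_max}]"
        )
    if phiR == p.phiR_max:
        # supply is identically zero; the continuous limit drains the pool
        return 0.0
    if phiR == p.phiR_min:
        raise DegenerateAllocationError(
            "phiR = phiR_min: consumption vanishes for all a, the amino-acid "
            "pool grows without bound and no finite steady state exists"
        )

    f = lambda a: flux_residual(a, phiR, p)
    lo, hi = p.K_gamma * 1e-6, p.K_nu * 1e6
    # geometric expansion; f(lo) > 0 > f(hi) is guaranteed in exact arithmetic
    for _ in range(60):
        if f(lo) > 0:
            break
        lo *= 1e-3
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 1e3
    flo, fhi = f(lo), f(hi)
    if not (flo > 0 > fhi):
        raise SolverError(
            f"could not bracket flux balance for phiR={phiR}: "
            f"f({lo:g})={flo:g}, f({hi:g})={fhi:g}"
        )
    return brentq(f, lo, hi, rtol=max(tol, 4e-16), xtol=1e-300)


def growth_rate_at(phiR: float, p: GrowthParams, tol: float = DEFAULT_TOL) -> float:
    """Steady-state growth rate lambda(phi_R) = gamma(a*(phi_R)) * (phi_R - phiR_min).

    Continuous on the closed partition interval, vanishing at both bounds:
    at ``phiR_min`` there are no active ribosomes, at ``phiR_max`` the pool
    drains (``a* = 0``) and translation starves.
    """
    if phiR == p.phiR_min:
        return 0.0
    if phiR == p.phiR_max:
        return 0.0
    a_star = solve_steady_amino_acid(phiR, p, tol=tol)
    return translation_flux(a_star, phiR, p)


def phiR_balance(a, p: GrowthParams):
    """Flux-balance curve phi_R as a function of the steady-state pool.

    Inverts the balance in closed form:
    ``phi_R(a) = [nu(a) phiR_max + gamma(a) phiR_min] / [nu(a) + gamma(a)]``.
    Non-increasing in ``a``, falling from ``phiR_max`` at a=0 to ``phiR_min``
    as a -> inf.
    """
    g = np.asarray(translational_efficiency(a, p), dtype=float)
    n = np.asarray(nutritional_efficiency(a, p), dtype=float)
    denom = g + n
    safe = np.where(denom > 0, denom, 1.0)
    out = np.where(denom > 0, (n * p.phiR_max + g * p.phiR_min) / safe, p.phiR_max)
    return out.item() if out.ndim == 0 else out


def closed_form_optimum(p: GrowthParams) -> tuple[float, float]:
    """Allocation and growth rate with both efficiencies at their maxima.

    Intersection of the two linear growth laws
    ``lambda = gamma0 (phi_R - phiR_min)`` and
    ``lambda = nu0 (phiR_max - phi_R)``; an upper bound on the achievable
    growth-rate maximum, attained only in the wide-plateau limit.

    Returns
    -------
    (phiR_hat, lambda_hat)
    """
    denom = p.gamma0 + p.nu0
    lambda_hat = p.gamma0 * p.nu0 * p.dphi / denom
    phiR_hat = (p.gamma0 * p.phiR_min + p.nu0 * p.phiR_max) / denom
    return phiR_hat, lambda_hat


def optimize_allocation(
    p: GrowthParams, tol: float = 1e-10, rel_tol: float = 0.10
) -> OptimumReport:
    """Maximize the steady-state growth rate over the ribosomal fraction.

    Uses bounded scalar minimization of ``-lambda(phi_R)`` on the open
    partition interval; the profile is unimodal so a derivative-free method
    converges.  A dense-grid fallback (with a warning) guards against a
    non-unimodal numerical profile, which should not occur.
    """
    if p.nu0 == 0:
        return OptimumReport(
            phiR_opt=p.phiR_min, lambda_opt=0.0, a_opt=0.0,
            phiR_hat=p.phiR_min, lambda_hat=0.0,
            plateau_a=(0.0, 0.0), plateau_phiR=(p.phiR_min, p.phiR_min),
            rel_tol=rel_tol,
        )

    eps = 1e-9 * p.dphi
    lo, hi = p.phiR_min + eps, p.phiR_max - eps
    res = minimize_scalar(
        lambda x: -growth_rate_at(x, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol * p.dphi},
    )
    phiR_opt, lambda_opt = float(res.x), -float(res.fun)

    # guard: dense grid, refine if the scalar solver was trapped
    grid = np.linspace(lo, hi, 201)
    lam_grid = np.array([growth_rate_at(x, p) for x in grid])
    k = int(np.argmax(lam_grid))
    if lam_grid[k] > lambda_opt * (1 + 1e-8):
        warnings.warn(
            "growth-rate profile appears non-unimodal; refining from grid",
            RuntimeWarning,
        )
        lo2, hi2 = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda x: -growth_rate_at(x, p), bounds=(lo2, hi2),
            method="bounded", options={"xatol": tol * p.dphi},
        )
        phiR_opt, lambda_opt = float(res.x), -float(res.fun)

    a_opt = solve_steady_amino_acid(phiR_opt, p)
    phiR_hat, lambda_hat = closed_form_optimum(p)
    pa, pphi = plateau_band(p, rel_tol=rel_tol, phiR_opt=phiR_opt)
    return OptimumReport(
        phiR_opt=phiR_opt, lambda_opt=lambda_opt, a_opt=a_opt,
        phiR_hat=phiR_hat, lambda_hat=lambda_hat,
        plateau_a=pa, plateau_phiR=pphi, rel_tol=rel_tol,
    )


def plateau_band(
    p: GrowthParams, rel_tol: float = 0.10, phiR_opt: float | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Optimality plateau: pool interval where flux balance stays near-optimal.

    Returns the connected interval of steady-state pool sizes over which the
    flux-balance curve ``phi_R(a*)`` remains within ``rel_tol`` (relative) of
    the optimal ribosomal fraction, together with the corresponding phi_R
    band.  The wider the separation ``K_nu / K_gamma``, the wider the
    plateau — this is what makes the regulation robust.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must be in (0, 1)")
    if phiR_opt is None:
        eps = 1e-9 * p.dphi
        res = minimize_scalar(
            lambda x: -growth_rate_at(x, p),
            bounds=(p.phiR_min + eps, p.phiR_max - eps),
            method="bounded", options={"xatol": 1e-10 * p.dphi},
        )
        phiR_opt = float(res.x)

    phi_hi = min(phiR_opt * (1 + rel_tol), p.phiR_max)
    phi_lo = max(phiR_opt * (1 - rel_tol), p.phiR_min)

    a_min, a_max = p.K_gamma * 1e-9, p.K_nu * 1e9
    # phiR_balance decreases from phiR_max to phiR_min over [0, inf)
    def g(a, target):
        return phiR_balance(a, p) - target

    # lower edge in a: where the balance curve crosses the upper phi bound
    if phi_hi >= p.phiR_max:
        a_lo = 0.0
    else:
        a_lo = brentq(g, a_min, a_max, args=(phi_hi,), rtol=1e-12)
    if phi_lo <= p.phiR_min:
        a_hi = float("inf")
    else:
        a_hi = brentq(g, a_min, a_max, args=(phi_lo,), rtol=1e-12)
    return (a_lo, a_hi), (phi_lo, phi_hi)


def make_steady_state(a_star: float, phiR_star: float, p: GrowthParams,
                      converged: bool = True) -> SteadyState:
    """Assemble a :class:`SteadyState` with fluxes evaluated at (a*, phi_R*)."""
    s = supply_flux(a_star, phiR_star, p)
    c = translation_flux(a_star, phiR_star, p)
    return SteadyState(
        a_star=float(a_star), phiR_star=float(phiR_star),
        lambda_star=float(c), supply=float(s), consumption=float(c),
        converged=converged, residual=float(s - c),
    )
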