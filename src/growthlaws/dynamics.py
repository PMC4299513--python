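"""Supply-driven activation of ribosome synthesis: dynamics, fixed point, stability.

The regulated system is two-dimensional.  The amino-acid pool obeys

    da/dt = beta * [nu(a) (phiR_max - phi_R) - lambda] - a * lambda,

where the last term is dilution by growth (it arises from normalizing the
pool by total protein mass), and the ribosomal fraction relaxes toward the
allocation prescribed by the control function chi_R:

    dphi_R/dt = lambda * (chi_R(a) - phi_R),

with lambda = gamma(a) * max(phi_R - phiR_min, 0).  The control function
chi_R(a) is the fraction of active ribosomes synthesizing ribosomal protein;
supply-driven activation means it is non-decreasing in the pool size.  At
steady state chi_R(a*) = phi_R* — the allocation rule coincides with the
realized proteome fraction.

Because the flux-balance curve phi_R(a*) is non-increasing and chi_R is
non-decreasing, a monotone control function intersects it exactly once, and
that intersection is a stable attractor (verified numerically here via the
Jacobian and multi-start integration).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import (
    GrowthParams,
    nutritional_efficiency,
    translational_efficiency,
)
from .steady_state import SteadyState, make_steady_state

__all__ = [
    "ControlFunction",
    "Trajectory",
    "FixedPointError",
    "make_control_function",
    "ode_rhs",
    "simulate",
    "find_fixed_point",
    "stability",
]

#: dense log-spaced sample used to validate monotonicity of control functions
_VALIDATION_GRID = np.logspace(-9, 0, 400)


class FixedPointError(RuntimeError):
    """No admissible intersection between control function and flux balance."""


@dataclass(frozen=True)
class ControlFunction:
    """A validated ribosome-synthesis allocation rule a -> chi_R(a).

    Non-decreasing with range in [0, 1]; monotonicity is checked on a dense
    logarithmic sample at construction.  ``family`` records provenance
    ("hill", "piecewise-linear", "constant", "table"); a constant rule is
    flagged ``unregulated`` — the paper's no-regulation contrast.
    """

    family: str
    params: dict
    func: Callable[[np.ndarray], np.ndarray]

    def __call__(self, a):
        return self.func(np.asarray(a, dtype=float))

    @property
    def unregulated(self) -> bool:
        return self.family == "constant"


def make_control_function(family: str, **params) -> ControlFunction:
    """Build and validate a control function.

    Families
    --------
    hill
        ``chi(a) = baseline + amplitude * a^h / (K_chi^h + a^h)``;
        parameters ``baseline`` (>=0), ``amplitude`` (>=0), ``K_chi`` (>0),
        ``h`` (>=1, default 2).  Amplitude 0 degenerates to a constant.
    constant
        ``chi(a) = value``; the unregulated contrast.
    piecewise-linear / table
        ``a_points``, ``chi_points``: interpolated, held flat outside the
        points.  A decreasing table is rejected — it would violate
        supply-driven activation.
    """
    if family == "hill":
        baseline = float(params.get("baseline", 0.0))
        amplitude = float(params.get("amplitude", 0.5))
        K_chi = float(params.get("K_chi", 1e-3))
        h = float(params.get("h", 2.0))
        if baseline < 0 or amplitude < 0 or K_chi <= 0 or h < 1:
            raise ValueError("hill control requires baseline, amplitude >= 0, K_chi > 0, h >= 1")
        if baseline + amplitude > 1:
            raise ValueError("control function range exceeds 1")
        func = lambda a: baseline + amplitude * a**h / (K_chi**h + a**h)
        spec = {"baseline": baseline, "amplitude": amplitude, "K_chi": K_chi, "h": h}
    elif family == "constant":
        value = float(params["value"])
        if not 0 <= value <= 1:
            raise ValueError("constant control value must lie in [0, 1]")
        func = lambda a: np.full_like(np.asarray(a, dtype=float), value)[()]
        spec = {"value": value}
    elif family in ("piecewise-linear", "table"):
        a_pts = np.asarray(params["a_points"], dtype=float)
        chi_pts = np.asarray(params["chi_points"], dtype=float)
        if a_pts.ndim != 1 or a_pts.shape != chi_pts.shape or a_pts.size < 2:
            raise ValueError("need matching 1-D a_points/chi_points with >= 2 entries")
        if np.any(np.diff(a_pts) <= 0):
            raise ValueError("a_points must be strictly increasing")
        if np.any(np.diff(chi_pts) < 0):
            raise ValueError(
                "decreasing control table violates supply-driven activation"
            )
        if np.any(chi_pts < 0) or np.any(chi_pts > 1):
            raise ValueError("control values must lie in [0, 1]")
        func = lambda a: np.interp(a, a_pts, chi_pts)
        spec = {"a_points": a_pts, "chi_points": chi_pts}
    else:
        raise ValueError(f"unknown control-function family {family!r}")

    vals = np.asarray(func(_VALIDATION_GRID), dtype=float)
    if np.any(np.diff(vals) < -1e-12):
        raise ValueError("control function must be non-decreasing in a")
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValueError("control function range must stay within [0, 1]")
    return ControlFunction(family=family, params=spec, func=func)


@dataclass(frozen=True)
class Trajectory:
    """Time course of the regulated system on a logarithmic output grid."""

    t: np.ndarray
    a: np.ndarray
    phiR: np.ndarray
    lam: np.ndarray
    converged: bool
    steady_state: SteadyState | None = None


def _growth_rate(a, phiR, p: GrowthParams):
    """lambda with phi_R clamped at phiR_min so transients below the offset are inert."""
    return translational_efficiency(a, p) * np.maximum(phiR - p.phiR_min, 0.0)


def ode_rhs(state, p: GrowthParams, chi: ControlFunction,
            dilution: bool = True) -> tuple[float, float]:
    """Right-hand side of the regulated two-variable system.

    ``dilution=False`` drops the -a*lambda term (negligible for a << 1);
    the default keeps the exact mass-fraction normalization.
    """
    a, phiR = state
    a = max(float(a), 0.0)  # integrators may undershoot zero by roundoff
    lam = _growth_rate(a, phiR, p)
    # metabolic sector clamped at zero (as lambda is below phiR_min) so the
    # rhs is total — and the pool stays non-negative — on all of [0, 1]
    phiP = max(p.phiR_max - phiR, 0.0)
    da = p.beta * (nutritional_efficiency(a, p) * phiP - lam)
    if dilution:
        da -= a * lam
    dphiR = lam * (float(chi(a)) - phiR)
    return (float(da), float(dphiR))


def simulate(
    initial: tuple[float, float],
    chi: ControlFunction,
    p: GrowthParams,
    t_end: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    n_out: int = 200,
    conv_tol: float = 1e-12,
    dilution: bool = True,
) -> Trajectory:
    """Integrate from ``initial = (a0, phiR0)`` with a stiff-capable solver.

    Stops early when the right-hand-side norm falls below ``conv_tol``
    (event-based convergence detection).  Output is reported on a log-spaced
    time grid plus t=0.
    """
    a0, phiR0 = initial
    if a0 < 0 or not 0 <= phiR0 <= 1:
        raise ValueError("initial state must satisfy a >= 0, 0 <= phiR <= 1")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    def rhs(t, y):
        return ode_rhs(y, p, chi, dilution=dilution)

    def settled(t, y):
        da, dphi = ode_rhs(y, p, chi, dilution=dilution)
        return float(np.hypot(da, dphi)) - conv_tol

    settled.terminal = True
    settled.direction = -1

    t_eval = np.concatenate([[0.0], np.geomspace(1e-4 * t_end, t_end, n_out - 1)])
    sol = solve_ivp(
        rhs, (0.0, t_end), [a0, phiR0], method="LSODA",
        t_eval=t_eval, events=settled, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0}: {sol.message}"
        )

    t, (a, phiR) = sol.t, sol.y
    if sol.t_events[0].size:  # append the event state
        t = np.append(t, sol.t_events[0][0])
        a = np.append(a, sol.y_events[0][0][0])
        phiR = np.append(phiR, sol.y_events[0][0][1])
    lam = _growth_rate(a, phiR, p)
    converged = bool(sol.t_events[0].size) or settled(t[-1], (a[-1], phiR[-1])) < 0
    ss = make_steady_state(a[-1], min(max(phiR[-1], p.phiR_min), p.phiR_max), p) \
        if converged else None
    return Trajectory(t=t, a=a, phiR=phiR, lam=lam, converged=converged,
                      steady_state=ss)


def _phiR_balance_dynamic(a, p: GrowthParams, dilution: bool = True):
    """Invert da/dt = 0 for phi_R, including the dilution correction.

    With dilution the pool balance reads
    nu(a)(phiR_max - phiR) = lambda (1 + a/beta), giving

        phi_R(a) = [nu phiR_max + gamma (1 + a/beta) phiR_min]
                   / [nu + gamma (1 + a/beta)];

    dropping dilution (a/beta -> 0) recovers the pure flux-balance curve.
    """
    g = translational_efficiency(a, p)
    n = nutritional_efficiency(a, p)
    w = 1.0 + (np.asarray(a) / p.beta if dilution else 0.0)
    denom = n + g * w
    return (n * p.phiR_max + g * w * p.phiR_min) / denom


def find_fixed_point(
    chi: ControlFunction,
    p: GrowthParams,
    tol: float = 1e-12,
    dilution: bool = True,
) -> SteadyState:
    """Locate the steady state of the regulated system.

    Solves chi_R(a) = phi_R^balance(a) in ``a`` by 1-D root finding; the
    left side is non-decreasing and the right side non-increasing, so the
    intersection is unique.  ``phi_R^balance`` inverts the pool balance in
    closed form (with the dilution correction when ``dilution=True``, so the
    result is an exact fixed point of :func:`ode_rhs`).

    Raises
    ------
    FixedPointError
        If the control function lies entirely above or below the balance
        curve on the admissible range, naming the failing side.
    """
    def g(a):
        return float(chi(a)) - float(_phiR_balance_dynamic(a, p, dilution))

    lo, hi = p.K_gamma * 1e-9, p.K_nu * 1e9
    glo, ghi = g(lo), g(hi)
    if glo > 0:
        raise FixedPointError(
            "control function lies above the flux-balance curve even at "
            f"vanishing pool (chi({lo:g}) = {float(chi(lo)):.4f} > balance); "
            "no intersection — allocation always exceeds what supply sustains"
        )
    if ghi < 0:
        raise FixedPointError(
            "control function lies below the flux-balance curve even at "
            f"saturating pool (chi({hi:g}) = {float(chi(hi)):.4f} < balance); "
            "no intersection — allocation never catches up with supply"
        )
    a_star = brentq(g, lo, hi, rtol=max(tol, 4e-16), xtol=1e-300)
    phiR_star = float(chi(a_star))
    ss = make_steady_state(a_star, phiR_star, p)
    if dilution:
        # residual field reports the exact ODE balance, not the undiluted one
        da, dphi = ode_rhs((a_star, phiR_star), p, chi, dilution=True)
        ss = replace(ss, residual=float(np.hypot(da, dphi)))
    return ss


def stability(
    ss: SteadyState,
    chi: ControlFunction,
    p: GrowthParams,
    rel_step: float = 1e-6,
    dilution: bool = True,
    rhs_tol: float = 1e-8,
) -> SteadyState:
    """Linear stability of a fixed point via a finite-difference Jacobian.

    Central differences with relative step ``rel_step`` on each state
    variable; the state is stable iff both eigenvalues have negative real
    part.  Returns a copy of ``ss`` with ``eigenvalues`` and ``stable``
    filled in.

    Raises
    ------
    ValueError
        If ``ss`` is not actually a fixed point of the dynamics.
    """
    x0 = np.array([ss.a_star, ss.phiR_star], dtype=float)
    f0 = np.array(ode_rhs(x0, p, chi, dilution=dilution))
    scale = max(abs(ss.lambda_star), 1.0)
    if np.linalg.norm(f0) > rhs_tol * scale:
        raise ValueError(
            f"state is not a fixed point: |rhs| = {np.linalg.norm(f0):g}"
        )
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_step * max(abs(x0[j]), 1e-12)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = np.array(ode_rhs(xp, p, chi, dilution=dilution))
        fm = np.array(ode_rhs(xm, p, chi, dilution=dilution))
        J[:, j] = (fp - fm) / (2 * h)
    eig = np.linalg.eigvals(J)
    stable = bool(np.all(eig.real < 0))
    return replace(ss, eigenvalues=(complex(eig[0]), complex(eig[1])),
                   stable=stable)
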