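"""Parameterization and algebraic rate laws of the coarse-grained growth model.

The model partitions the proteome into a ribosomal fraction ``phi_R`` and a
metabolic fraction ``phi_P`` subject to ``phi_R + phi_P = phiR_max``, and
tracks a single growth-limiting free amino-acid pool ``a`` (mass of the pool
normalized by total protein mass).  Two lumped efficiencies govern the fluxes
through this pool:

* the translational efficiency ``gamma(a)`` — peptide elongation per unit
  ribosomal protein mass, attenuated when the pool drops below ``K_gamma``
  (tRNA charging becomes limiting);
* the nutritional efficiency ``nu(a)`` — amino-acid supply per unit metabolic
  protein mass, attenuated by end-product feedback inhibition when the pool
  rises above ``K_nu``.

Both are modeled as simple Hill-type sigmoids with configurable exponents
(defaults 1).  Growth rate follows from protein synthesis,
``lambda = gamma(a) * (phi_R - phiR_min)``, where ``phiR_min`` is the
growth-rate-independent ribosomal offset (inactive ribosomes etc.).

All rates are in 1/hour; pools and proteome fractions are dimensionless mass
fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "DomainError",
    "translational_efficiency",
    "nutritional_efficiency",
    "translation_flux",
    "supply_flux",
    "flux_residual",
]


class DomainError(ValueError):
    """An argument lies outside the model's physical domain."""


@dataclass(frozen=True)
class GrowthParams:
    """Rate-law constants and proteome-partition bounds.

    Attributes
    ----------
    gamma0 : float
        Maximal translational efficiency (1/h), set by the medium and any
        translation-inhibiting antibiotics.
    nu0 : float
        Maximal nutritional efficiency (1/h), set by nutrient quality.
    K_gamma : float
        Amino-acid mass fraction below which translation attenuates.
    K_nu : float
        Amino-acid mass fraction above which supply is feedback-inhibited.
    phiR_min : float
        Growth-rate-independent ribosomal offset fraction.
    phiR_max : float
        Maximum ribosomal fraction (``phi_R + phi_P = phiR_max``).
    beta : float
        Fraction of translation events consuming the limiting amino acid
        (1 in scaled units).
    h_gamma, h_nu : float
        Hill exponents of the two sigmoids.
    """

    gamma0: float
    nu0: float
    K_gamma: float = 1e-4
    K_nu: float = 5e-4
    phiR_min: float = 0.07
    phiR_max: float = 0.55
    beta: float = 1.0
    h_gamma: float = 1.0
    h_nu: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma0 > 0:
            raise ValueError(f"gamma0 must be > 0, got {self.gamma0}")
        if not self.nu0 >= 0:
            raise ValueError(f"nu0 must be >= 0, got {self.nu0}")
        if not self.K_gamma > 0:
            raise ValueError(f"K_gamma must be > 0, got {self.K_gamma}")
        if not self.K_nu > 0:
            raise ValueError(f"K_nu must be > 0, got {self.K_nu}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0 <= self.phiR_min < self.phiR_max <= 1:
            raise ValueError(
                "require 0 <= phiR_min < phiR_max <= 1, got "
                f"phiR_min={self.phiR_min}, phiR_max={self.phiR_max}"
            )
        if not self.h_gamma >= 1:
            raise ValueError(f"h_gamma must be >= 1, got {self.h_gamma}")
        if not self.h_nu >= 1:
            raise ValueError(f"h_nu must be >= 1, got {self.h_nu}")

    @property
    def dphi(self) -> float:
        """Width of the growth-rate-dependent proteome sector."""
        return self.phiR_max - self.phiR_min

    def replace(self, **changes) -> "GrowthParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


def _check_a(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise DomainError("amino-acid level a must be >= 0")
    return a


def _check_phiR(phiR, p: GrowthParams) -> np.ndarray:
    phiR = np.asarray(phiR, dtype=float)
    if np.any(phiR < p.phiR_min) or np.any(phiR > p.phiR_max):
        raise DomainError(
            f"phiR must lie in [{p.phiR_min}, {p.phiR_max}], got {phiR}"
        )
    return phiR


def translational_efficiency(a, p: GrowthParams):
    """Translational efficiency gamma(a) = gamma0 * a^h / (K_gamma^h + a^h).

    Non-decreasing in ``a``, bounded by ``gamma0``; half-maximal at
    ``a = K_gamma`` for Hill exponent 1.  Accepts scalars or arrays.
    """
    a = _check_a(a)
    h = p.h_gamma
    # a^h / (K^h + a^h) rewritten for numerical safety at large a;
    # (K/a)^h may overflow to inf for tiny a, which correctly yields 0
    with np.errstate(divide="ignore", over="ignore"):
        ratio = (p.K_gamma / np.where(a > 0, a, np.nan)) ** h
    out = np.where(a > 0, p.gamma0 / (1.0 + ratio), 0.0)
    return out.item() if out.ndim == 0 else out


def nutritional_efficiency(a, p: GrowthParams):
    """Nutritional efficiency nu(a) = nu0 * K_nu^h / (K_nu^h + a^h).

    Non-increasing in ``a``, bounded by ``nu0``; half-inhibited at
    ``a = K_nu`` for Hill exponent 1.
    """
    a = _check_a(a)
    out = p.nu0 / (1.0 + (a / p.K_nu) ** p.h_nu)
    return out.item() if np.ndim(out) == 0 else out


def translation_flux(a, phiR, p: GrowthParams):
    """Protein-synthesis flux, identified with the growth rate.

    lambda = gamma(a) * (phi_R - phiR_min); zero iff ``a == 0`` or
    ``phi_R == phiR_min``.
    """
    phiR = _check_phiR(phiR, p)
    return translational_efficiency(a, p) * (phiR - p.phiR_min)


def supply_flux(a, phiR, p: GrowthParams):
    """Amino-acid supply flux nu(a) * (phiR_max - phi_R), in growth-rate units.

    Supply is carried by the metabolic sector ``phi_P = phiR_max - phi_R``:
    allocating more proteome to ribosomes necessarily starves supply.
    """
    phiR = _check_phiR(phiR, p)
    return nutritional_efficiency(a, p) * (p.phiR_max - phiR)


def flux_residual(a, phiR, p: GrowthParams):
    """Signed flux imbalance: supply minus consumption (1/h).

    Strictly decreasing in ``a`` for interior ``phi_R`` (supply is
    non-increasing, consumption non-decreasing), hence it has exactly one
    sign change — the flux-balance point.
    """
    return supply_flux(a, phiR, p) - translation_flux(a, phiR, p)
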