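"""Presets, config-file loading, and the synthetic growth-table generator.

The model has no external data formats of its own; parameters arrive either
from named presets (the illustration parameter sets: translational
efficiency 5.9/h, partition bounds 0.07/0.55, attenuation thresholds
K_gamma = 1e-4 with K_nu = 5e-4 for the narrow-plateau set or 5e-3 for the
wide-plateau set, nutrient qualities 2.5 / 3.3 / 5.8 per hour) or from a
small YAML config whose keys mirror the parameter names.  Outputs are tidy
CSV tables and JSON reports.

The synthetic generator emulates growth-law measurement campaigns: a panel
of media of varying nutrient quality (or antibiotic doses of varying
translational inhibition), steady states computed from the regulated model,
and Gaussian measurement noise added to the ribosomal fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GrowthParams
from .dynamics import ControlFunction, find_fixed_point, make_control_function
from .phenomenology import standard_control
from .steady_state import plateau_band

__all__ = [
    "PRESETS",
    "get_preset",
    "load_config",
    "SyntheticGrowthTable",
    "generate_synthetic_table",
    "sample_control_family",
]

#: nutrient qualities used in the worked illustrations (poor / good / rich media)
PRESET_NU0 = (2.5, 3.3, 5.8)

PRESETS: dict[str, GrowthParams] = {
    # narrow plateau: K_nu = 5 * K_gamma
    "fig2": GrowthParams(gamma0=5.9, nu0=2.5, K_gamma=1e-4, K_nu=5e-4,
                         phiR_min=0.07, phiR_max=0.55),
    # wide plateau: K_nu = 50 * K_gamma
    "fig3": GrowthParams(gamma0=5.9, nu0=2.5, K_gamma=1e-4, K_nu=5e-3,
                         phiR_min=0.07, phiR_max=0.55),
    # plateau limit: thresholds separated by 1e5, for growth-law recovery
    "wide": GrowthParams(gamma0=5.9, nu0=2.5, K_gamma=1e-6, K_nu=1e-1,
                         phiR_min=0.07, phiR_max=0.55),
}


def get_preset(name: str, **overrides) -> GrowthParams:
    """Fetch a named preset, optionally overriding fields (e.g. nu0=5.8)."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return p.replace(**overrides) if overrides else p


_PARAM_KEYS = {f.name for f in dataclasses.fields(GrowthParams)}
_OPTION_KEYS = {"tol", "seed", "t_end", "out"}


def load_config(path) -> tuple[GrowthParams, dict]:
    """Read a YAML config into validated parameters plus run options.

    Recognized keys: ``preset`` (expanded first, then overridden by any
    explicit parameter keys), the parameter names themselves
    (gamma0, nu0, K_gamma, K_nu, phiR_min, phiR_max, beta, h_gamma, h_nu),
    and the run options tol / seed / t_end / out.  Unknown keys are
    rejected; invariant violations name the failing field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")

    unknown = set(raw) - _PARAM_KEYS - _OPTION_KEYS - {"preset"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    base = {}
    if "preset" in raw:
        base = dataclasses.asdict(get_preset(raw["preset"]))
    for k in _PARAM_KEYS & set(raw):
        base[k] = float(raw[k])
    if "gamma0" not in base or "nu0" not in base:
        raise ValueError("config must set gamma0 and nu0 (directly or via preset)")
    params = GrowthParams(**base)
    options = {k: raw[k] for k in _OPTION_KEYS & set(raw)}
    return params, options


@dataclass(frozen=True)
class SyntheticGrowthTable:
    """A reproducible synthetic (growth rate, ribosomal fraction) dataset.

    ``table`` has one row per condition: the varied efficiency, the
    noise-free steady state, and the noisy measurement ``phiR_obs``.
    """

    mode: str                 # "nutrient" | "translation"
    true_params: GrowthParams
    noise_sd: float
    seed: int
    table: pd.DataFrame


def generate_synthetic_table(
    true_params: GrowthParams | None = None,
    n: int = 20,
    noise_sd: float = 0.01,
    seed: int = 0,
    mode: str = "nutrient",
    efficiency_range: tuple[float, float] = (0.1, 10.0),
    chi: ControlFunction | None = None,
) -> SyntheticGrowthTable:
    """Simulate a growth-law measurement campaign.

    Conditions are drawn log-uniformly over ``efficiency_range``: nutrient
    qualities nu0 in 1/h for ``mode="nutrient"`` (default 0.1–10/h, doubling
    times from ~25 min to several days, bracketing the poor/good/rich
    illustration media), or multiplicative factors on gamma0 for
    ``mode="translation"`` (interpreted relative to a range cap of 1).
    Each condition's steady state comes from the regulated system; Gaussian
    noise with standard deviation ``noise_sd`` is then added to phi_R only —
    growth rate is measured far more precisely than proteome composition.
    """
    if n < 3:
        raise ValueError("need at least 3 conditions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if true_params is None:
        true_params = PRESETS["wide"]
    rng = np.random.default_rng(seed)
    lo, hi = efficiency_range
    values = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    values.sort()

    if chi is None:
        chi = standard_control(true_params)

    rows = []
    for i, v in enumerate(values):
        if mode == "nutrient":
            p_i = true_params.replace(nu0=float(v))
            varied = {"nu0": float(v)}
        elif mode == "translation":
            scale = float(min(v / hi, 1.0))  # map to (0, 1] multipliers
            p_i = true_params.replace(gamma0=true_params.gamma0 * scale)
            varied = {"gamma0": p_i.gamma0}
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ss = find_fixed_point(chi, p_i)
        rows.append({
            "condition": f"{mode}-{i:02d}", **varied,
            "lam": ss.lambda_star, "phiR_true": ss.phiR_star,
        })
    df = pd.DataFrame(rows)
    df["phiR_obs"] = df["phiR_true"] + rng.normal(0.0, noise_sd, size=n)
    return SyntheticGrowthTable(
        mode=mode, true_params=true_params, noise_sd=noise_sd,
        seed=seed, table=df,
    )


def sample_control_family(
    p: GrowthParams,
    n: int = 50,
    seed: int = 0,
    rel_tol: float = 0.10,
    max_draws: int = 10000,
) -> list[ControlFunction]:
    """Draw a seeded family of monotone hill control rules crossing the plateau.

    Emulates the "broad spectrum of putative control functions" argument:
    any supply-driven-activation rule whose graph traverses the optimality
    plateau pins the steady state near the growth-rate optimum, with no
    tuning of its shape.  Half-points are drawn log-uniformly inside the
    plateau's pool interval, Hill exponents uniformly in [1, 4], baselines
    below the plateau's phi_R band and saturation values above it; draws
    that fail to cross the plateau band (possible for shallow exponents)
    are rejected.
    """
    (a_lo, a_hi), (phi_lo, phi_hi) = plateau_band(p, rel_tol=rel_tol)
    if not (a_lo > 0 and np.isfinite(a_hi) and a_hi > a_lo):
        raise ValueError("plateau interval is degenerate for these parameters")
    rng = np.random.default_rng(seed)
    family: list[ControlFunction] = []
    for _ in range(max_draws):
        if len(family) >= n:
            break
        baseline = rng.uniform(0.0, 0.5 * phi_lo)
        top = rng.uniform(phi_hi, p.phiR_max)
        K_chi = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi)))
        h = rng.uniform(1.0, 4.0)
        chi = make_control_function(
            "hill", baseline=baseline, amplitude=top - baseline,
            K_chi=K_chi, h=h,
        )
        # crossing condition: below the band at its left edge, above at its
        # right edge -> the intersection with flux balance lies inside it
        if float(chi(a_lo)) <= phi_lo and float(chi(a_hi)) >= phi_hi:
            family.append(chi)
    if len(family) < n:
        raise RuntimeError(
            f"only {len(family)} of {n} draws crossed the plateau; "
            "widen the threshold separation or relax rel_tol"
        )
    return family
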