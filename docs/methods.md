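# Methods

## Model

`growthlaws` implements a two-sector proteome-allocation model of balanced
exponential bacterial growth. Total protein mass is split into a
growth-rate-independent sector and two adjustable sectors — ribosomal
(mass fraction φ_R) and metabolic (φ_P) — under the partition constraint
φ_R + φ_P = φ_R^max. A single coarse-grained, growth-limiting amino-acid
pool, expressed as the mass fraction a (pool mass over total protein mass),
links the two sectors:

- **Consumption** (protein synthesis, identified with growth):
  λ = γ(a) · (φ_R − φ_R^min), where γ is the translational efficiency —
  peptide elongation folded into a rate per unit ribosomal protein mass —
  and φ_R^min is the offset of inactive ribosomes.
- **Supply** (transport/biosynthesis): ν(a) · (φ_R^max − φ_R), where ν is
  the nutritional efficiency per unit metabolic protein mass.

Both efficiencies depend on the pool through simple sigmoids,

    γ(a) = γ₀ aʰ / (K_γʰ + aʰ),      ν(a) = ν₀ K_νʰ / (K_νʰ + aʰ),

capturing tRNA-charging limitation of elongation below K_γ and end-product
feedback inhibition of supply above K_ν. Hill activation/inhibition with
exponent 1 is the simplest form with the required limits; the exponents are
exposed (`h_gamma`, `h_nu`) for sharper switches, but all shipped presets
use 1, and any figure-shape comparison to the original illustrations is
qualitative only since only the limiting behavior is pinned down.

Pool dynamics follow from mass balance normalized by total protein mass:

    da/dt = β [ν(a)(φ_R^max − φ_R) − λ] − a·λ,

with β the fraction of translation events consuming the limiting amino acid
(default 1, i.e. scaled units — the figure-caption presets for ν₀ are then
used unmodified) and −a·λ the dilution of the pool by growth. Ribosome
synthesis is governed by a control function χ_R(a), the fraction of active
ribosomes making ribosomal protein:

    dφ_R/dt = λ (χ_R(a) − φ_R),

so that in steady state χ_R(a\*) = φ_R\* exactly. Supply-driven activation
means χ_R is non-decreasing: a swelling pool signals supply in excess of
demand and de-represses ribosome synthesis (the coarse abstraction of
ppGpp/rRNA control in *E. coli*; no molecular species is modeled).

## Steady states, optimum, plateau

For fixed φ_R strictly inside (φ_R^min, φ_R^max), flux balance
ν(a\*)(φ_R^max − φ_R) = γ(a\*)(φ_R − φ_R^min) has a unique root because the
left side is non-increasing in a and the right side non-decreasing. The
induced growth-rate curve λ(φ_R) vanishes at both partition bounds and has
a unique interior maximum (φ_R^opt, λ_opt). With both efficiencies at their
maxima the balance gives the closed-form bound

    λ̂ = γ₀ν₀(φ_R^max − φ_R^min)/(γ₀ + ν₀),
    φ̂_R = (γ₀φ_R^min + ν₀φ_R^max)/(γ₀ + ν₀),

which λ_opt approaches from below as K_ν/K_γ → ∞ (relative gap ≈0.9% at a
ratio of 10⁴ with exponents 1).

Inverting the balance gives the flux-balance curve
φ_R(a) = [ν(a)φ_R^max + γ(a)φ_R^min]/[ν(a) + γ(a)], which falls from
φ_R^max to φ_R^min. The *optimality plateau* is the connected interval of a
over which this curve stays within a relative tolerance (default 10%, the
illustration's value, exposed as `rel_tol`) of φ_R^opt; it is reported both
in a-space and as the corresponding φ_R band. The wider the separation
K_γ ≪ K_ν, the wider the plateau, and the less the realized allocation
depends on the exact shape of χ_R — this is the robustness mechanism by
which the empirical growth laws emerge without fine-tuning.

## Fixed point of the regulated system

`find_fixed_point` solves χ_R(a) = φ_R^balance(a) in one dimension. Because
the dilution term −a·λ is retained in the ODE by default, the balance curve
used here carries the matching correction,

    φ_R^balance(a) = [ν(a)φ_R^max + γ(a)(1 + a/β)φ_R^min]
                     / [ν(a) + γ(a)(1 + a/β)],

so the returned state is an exact fixed point of the integrated dynamics
(the two agree to machine precision, and trajectories match the fixed point
to better than 10⁻⁶ relative). Setting `dilution=False` in both drops the
correction — the shift is O(a\*) ≈ 0.1% relative for physiological pools —
and recovers the pure flux-balance form; the toggle exists because the
undiluted algebra is the cleaner pedagogical object.

Monotonicity (χ_R non-decreasing, φ_R^balance non-increasing) makes the
intersection unique. Stability is assessed numerically: a 2×2 Jacobian by
central finite differences (relative step 10⁻⁶) and its eigenvalues; the
analytic global-stability argument is out of scope, so the package verifies
stability per parameter set rather than proving it. In every tested
configuration (seeded sweeps over monotone Hill control functions) both
eigenvalues have negative real part and multi-start integrations converge
to the same point.

## Emergent growth laws and Monod kinetics

When the steady-state pool sits on the plateau, γ ≈ γ₀ and ν ≈ ν₀, and the
flux constraints alone force the two linear laws:

- nutrient sweep (vary ν₀): φ_R = φ_R^min + λ/γ₀ (slope 1/γ₀);
- translation sweep (scale γ₀ down, the antibiotic proxy): φ_R = φ_R^max −
  λ/ν₀ (slope −1/ν₀).

The sweep functions generate each point from the *regulated* fixed point
under one generic control function (`standard_control`: Hill from 0 to
φ_R^max, half-point at the geometric mean of K_γ and K_ν, exponent 2 — a
shape chosen to cross the flux-balance curve for any admissible parameters,
not tuned to any medium), since the claim being demonstrated is that the
regulation, not an optimizer, produces the laws. `use_optimizer=True`
switches to the idealized maximum for comparison. Recovery of slope and
intercept tightens as the threshold separation grows; the shipped "wide"
preset (K_γ = 10⁻⁶, K_ν = 10⁻¹) keeps the systematic plateau bias in the
fitted efficiencies below ~0.5%.

For transport-limited supply the transporter efficacy takes a Michaelis
form in the external substrate, k_a = k_cat·a_ex/(K_M + a_ex), making the
saturating nutritional efficiency ν(a_ex) = ν_∞·a_ex/(K_M + a_ex) with
ν_∞ = k_cat (expression level folded in). Substituting into the balanced
fluxes and eliminating φ_R through λ = γ(φ_R − φ_R^min):

    λ = γ ν(a_ex) Δφ / (γ + ν(a_ex))
      = [γ ν_∞ Δφ/(γ + ν_∞)] · a_ex / (a_ex + K_M γ/(γ + ν_∞)),

i.e. a Monod relation λ = λ_∞ a_ex/(a_ex + K_M^app) with

    λ_∞ = γ ν_∞ Δφ/(γ + ν_∞),      K_M^app = K_M · γ/(γ + ν_∞).

The apparent Michaelis constant is always below the transporter's K_M and
inherits the growth-medium dependence through γ and ν_∞. γ enters at γ₀
(plateau conditions).

Unit conversions use φ_i = σ·c_i·N_aa with σ = 3.8×10⁻⁷ per µM per residue
(stored to the two printed significant figures; not re-derived from cell
density), so 1 mM of a one-residue species ↔ mass fraction 3.8×10⁻⁴, and a
330-residue protein at 0.1% of protein mass ↔ ≈8 µM.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `gamma0` | maximal translational efficiency | 1/h | preset 5.9 |
| `nu0` | maximal nutritional efficiency | 1/h | presets 2.5 / 3.3 / 5.8 |
| `K_gamma` | pool level attenuating translation | mass fraction | 10⁻⁴ |
| `K_nu` | pool level triggering supply inhibition | mass fraction | 5×10⁻⁴ (fig2), 5×10⁻³ (fig3) |
| `phiR_min` | inactive-ribosome offset | fraction | 0.07 |
| `phiR_max` | partition bound φ_R + φ_P | fraction | 0.55 |
| `beta` | limiting-amino-acid share of translation | — | 1 |
| `h_gamma`, `h_nu` | sigmoid sharpness | — | 1 |

Presets: `fig2` (narrow plateau, K_ν = 5K_γ), `fig3` (wide plateau,
K_ν = 50K_γ), `wide` (plateau limit, K_ν/K_γ = 10⁵, for growth-law
recovery studies).

## Synthetic data generator

`generate_synthetic_table` emulates a growth-law measurement campaign: a
panel of n media whose nutrient qualities ν₀ are drawn log-uniformly from
0.1–10/h (doubling times from ~25 min to several days, bracketing the
poor/good/rich preset media), steady states computed from the regulated
model under `standard_control`, and i.i.d. Gaussian noise (default sd 0.01)
added to φ_R only — proteome composition is the noisy measurement, growth
rate is comparatively precise. Defaults: n = 20 conditions, the `wide`
parameter set as ground truth. `mode="translation"` varies γ₀ instead at
fixed ν₀.

What it does *not* emulate: correlated or heteroscedastic measurement
error, noise in λ, day/batch effects, deviations of real regulation from
the model family, or media that shift γ₀ and ν₀ jointly. Passing recovery
tests therefore shows identifiability of (γ₀, φ_R^min) under the model's
own noise assumptions, not agreement with any experimental dataset. At the
stated noise level the OLS intercept has standard error ≈0.003 on
φ_R^min = 0.07, so recovery to a few percent is near the information limit
of a 20-point table.

## Numerical choices

- Flux-balance root finding: Brent's method on a bracket initialized at
  [K_γ·10⁻⁶, K_ν·10⁶] and expanded geometrically, because admissible pools
  span many decades; relative tolerance 10⁻¹² on a.
- φ_R exactly at a partition bound is legal input (fluxes vanish
  continuously); outside the bounds is a domain error, never clamped —
  silent clamping hides caller bugs. φ_R = φ_R^min has no finite
  flux-balance point (consumption is identically zero) and raises a
  dedicated degenerate-allocation error; φ_R = φ_R^max returns a\* = 0 as
  the continuous limit.
- Optimization: bounded derivative-free scalar maximization of λ(φ_R)
  (unimodal), with a dense-grid fallback that warns if the numerical
  profile ever looks non-unimodal.
- ODE integration: LSODA (stiff-capable) at rtol 10⁻¹⁰/atol 10⁻¹⁴, output
  on a log-spaced grid, with a terminal event when the right-hand-side norm
  falls below 10⁻¹². Inside the right-hand side λ is clamped to 0 for
  φ_R < φ_R^min and the metabolic sector to 0 for φ_R > φ_R^max, so the
  vector field is total on a ≥ 0, φ_R ∈ [0, 1] and that box is forward
  invariant; the model proper concerns φ_R^min ≤ φ_R ≤ φ_R^max.
- Jacobians are finite-difference rather than symbolic, keeping the
  rate-law forms swappable.
- Control functions are validated non-decreasing by dense log-spaced
  sampling at construction; a decreasing table is rejected outright.

## Problem sizes

The shipped tests and the reproduction script use small, fixed problem
sizes chosen to exercise every claim well inside interactive runtimes: a
10×10 (φ_R, ν₀) oracle grid, a 50-member seeded control-function family,
20 random starts for the attractor check, and 20-point synthetic tables.
All are package defaults, reproducible via the documented seeds.

## Limitations

- Two adjustable sectors and one scalar allocation variable; no
  multi-sector or stoichiometric (FBA-style) extension.
- Nutrient-shift protocols, adaptation dynamics, and single-cell
  stochasticity are out of scope; only relaxation to steady state is
  simulated.
- ppGpp, tRNA charging, and individual amino-acid species are represented
  only abstractly through χ_R(a), K_γ, and K_ν.
- Global stability is verified numerically per configuration, not proved.
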