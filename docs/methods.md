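# Methods

## Model structure

The model is a standard one-reserve, one-structure DEB with maturity
bookkeeping, extended with type-abj metabolic acceleration and a starvation
module. State: reserve `E` (J), structure `V` (cm³), maturity `E_H` (J),
reproductive buffer `E_R` (J). With `L = V^(1/3)`, `e = E/(V·[E_m])`,
`[E_m] = {p_Am}/v`, thermal correction `c = c_T(T)` and acceleration `M`:

    p_A = f · {p_Am} · c · M · L²          (0 for embryos, E_H < E_H^b)
    p_C = (E/V) · ([E_G]·v·c·M·L² + [p_M]·c·V) / ([E_G] + κ·E/V)
    p_J = k_J · c · E_H

Non-starving (`κ·p_C ≥ [p_M]·c·V`):

    p_S = [p_M]·c·V,   p_G = κ·p_C − p_S,   p_R = (1−κ)·p_C − p_J

Starving (`κ·p_C < [p_M]·c·V`): the maintenance demand is re-priced at the
starvation rate, growth is clamped to non-positive, and the unpaid remainder
is withdrawn from structure at the cost of structure:

    p_S = [p_M]^starv·c·V,   p_G = min(0, κ·p_C − p_S),   dV/dt = p_G/[E_G]

State dynamics: `dE/dt = p_A − p_C`, `dV/dt = p_G/[E_G]`; below puberty
`dE_H/dt = p_R` (negative allowed when `(1−κ)p_C < p_J`, floored at 0),
above puberty `dE_R/dt = p_R`, with maturity-maintenance deficits paid from
`E_R` while it lasts and only then from `E_H` (rejuvenation); puberty is
latched — once crossed the individual remains spawning-eligible. Mature
individuals empty `E_R` as gametes every `spawn_period = 365` d, with spawn
dates anchored at fertilization.

Acceleration: `M = 1` for embryos, `M = L/L_b` between birth and
metamorphosis (exponential larval growth), `M = L_j/L_b` frozen afterwards;
`L_b` and `L_j` are recorded at the threshold crossings of each simulation,
not fixed constants, so they respond to parameter changes. `M` multiplies
exactly the processes containing `{p_Am}` and `v`. The same `c_T` corrects
all rates (`{p_Am}`, `v`, `[p_M]`, `[p_M]^starv`, `k_J`), including the
starvation maintenance rate.

Observables: larval width `L/δ_larv` before metamorphosis, arm length
`L/δ_post` after; wet weight `W = d_V·V + w_E·(E + E_R)`; reproductive
output `RO = w_E·E_R/(d_V·V + w_E·E)` (somatic mass = structure + reserve);
composition fractions of wet weight for structure, reserve and gonad.

## Environment

`f = X/(X + X_K)` (Holling type II, `X_K = 13.9` mussels m⁻²), overridable
by a direct `f` column in the forcing. Thermal correction:

    c_T(T) = A(T) / max A,   A(T) = exp(T_A/T_ref − T_A/T) · s(T_ref)/s(T)
    s(T) = 1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T)

The normalization maximum is taken on a fixed grid, 276–302 K at 0.01 K, so
`c_T` is bit-for-bit reproducible; with the default thermal parameters the
curve peaks near 295.4 K and gives `c_T(285.15 K) = 0.439`,
`c_T(282.15 K) = 0.279`. The curve is calibrated on aquatic respirometry up
to ~26 °C; temperatures above ~295 K are simulated but flagged with a
warning. Forcing interpolation is piecewise-constant at daily resolution by
default (linear available); Celsius is accepted only at the I/O boundary.

## Parameters

Defaults (`data/pisaster_params.yaml`) follow published estimates for
*P. ochraceus*: covariation-method fits for the core DEB parameters and
direct fits for `X_K`, `T_A`, `[p_M]^starv` and `δ_post`. Units: J, cm, g,
d, K. Key values: `{p_Am} = 43.2 J d⁻¹cm⁻²`, `v = 0.04 cm d⁻¹`, `κ = 0.58`,
`[p_M] = 40.43`, `[p_M]^starv = 11.5 J d⁻¹cm⁻³`, `[E_G] = 2743 J cm⁻³`,
`E_H^b = 0.012 J`, `E_H^j = 100 J`, `k_J = 2.9e-6 d⁻¹`, `w_E = W_E/μ_E =
23.9/550000 g J⁻¹`.

**Maturity at puberty.** The shipped `E_H^p = 1.39e5 J` deviates from the
commonly printed `1.39e7 J`. With all other defaults, the printed magnitude
delays puberty to ~day 1371 at ~1.5 kg wet weight, incompatible with the
species' reported ad-libitum life history (puberty ≈ day 264 at ≈ 67 g),
while `1.39e5 J` (same mantissa, two decades lower — and the printed SD of
`9.9e7` is seven times the printed mean, so the magnitude carries little
information) yields day 241 at 54 g. We treat the printed value as a
transcription error; users who disagree can override it in the parameter
file.

## Numerics

Fixed-step RK4 with default `dt = 0.01 d` up to metamorphosis and
`0.05–0.5 d` after; output sampled daily. Maturity-threshold crossings are
located by linear interpolation within the step, the state is advanced to
the crossing, the stage mark recorded, and the remainder of the step
re-integrated under the new stage — so `M` and `p_A` switch exactly at the
event. Steps that would drive `E`, `V` or `E_R` negative are shortened
(linear estimate of the zero crossing, then re-stepped), not clamped; a
residual below round-off is snapped to zero. Structural volume below
`1e-12 cm³` or any non-finite state raises a death event / integration
fault and truncates the trajectory. Halving `dt` moves daily-sampled states
by well under 0.01%, and a 0.5-d RK4 run matches a `1e-3`-d explicit-Euler
oracle to better than 0.1% over 100 d.

Embryo initialization uses maternal matching: `V₀ = 1e-9 cm³`, `E_H = 0`,
and the egg energy `E₀` found by bisection (bracket `1e-4–1e2 J`, ≤60
iterations) so that the scaled reserve density at birth equals the mother's
expected feeding level within `1e-3`. Eggs below roughly half the matched
energy exhaust their reserve before feeding onset and are reported
infeasible.

A transient worth knowing: a *well-fed* individual deprived of food keeps
growing for one to two weeks (until `e` falls below `L/L_∞`), and because
converting reserve (`w_E ≈ 4.35e-5 g J⁻¹`) into structure (`1/[E_G] ≈
3.6e-4 g J⁻¹`) adds water-rich mass, wet weight can rise by a few grams
before the long exponential decline. Starvation-mode dynamics proper are
strictly non-increasing in both `V` and `W`.

## Calibration fits

- `fit_functional_response`: nonlinear least squares of `f = X/(X+X_K)`
  (scipy `curve_fit`); degenerate when all responses sit on the saturated
  plateau (`X_K` collapses far below the sampled densities).
- `fit_arrhenius_TA`: `T_A = −slope` of `ln(rate)` on `1/T`, restricted to a
  window (default 282–294 K) on the rising limb.
- `grid_search_tpc`: exhaustive grid (default 21 points/parameter, cap 2e6
  cells) over `T_L, T_H, T_AL, T_AH` with `T_A` fixed, minimizing RMSE
  between the max-scaled observed rates and the candidate curve max-scaled
  over the same temperatures (both sides scale-free, so the objective is
  invariant to uniform rescaling of the data); ties broken
  first-in-lexicographic order with a warning.
- `fit_p_M_starv`: per individual, bounded scalar minimization (1–40
  J d⁻¹cm⁻³) of the RMSE between observed wet weights and an `f = 0`
  simulation started from the first weighing at reserve density `e₀ = 1`;
  per-individual estimates are averaged. This fit inherits the shrinkage
  rule above (unpaid maintenance from structure at `[E_G]` per cm³): a
  different structure-to-energy yield would change the estimates.
- `fit_shape_coefficient`: least squares of the structural weight–length
  link `W = (δ·L_arm)³` (`d_V = 1`), which crosses a weight–length cloud
  below its center because reserve and gonad are excluded.

## Sensitivity, Monte Carlo, skill

Sensitivity is one-at-a-time ±10% on each parameter; the response is arm
length at age 2 y of a post-metamorphic individual at 13 °C and `f = 1`.
The 2-y clock starts at metamorphosis and the metamorphosis state is
re-derived per perturbed parameter set, so early-life parameters (e.g.
`E_H^b`) propagate; `δ_larv` and `[p_M]^starv` are exactly inert in this
scenario. `X_K` is evaluated at the finite density `X = 10·X_K` (at `f = 1`
exactly it is inert by construction). Infeasible perturbations (e.g. κ
above 1) are recorded as such, never skipped silently.

Monte Carlo draws parameters independently from per-parameter normals.
Several printed SDs exceed their means (`E_H^p`, `δ_larv`, `k_J`), which
makes joint rejection sampling infeasible — the `resample` policy therefore
aborts with diagnostics when more than half of the attempted draws violate
the invariants, and the default `truncnorm` policy samples each parameter
from the exact normal truncated to its feasible interval (scipy
`truncnorm`), logging repairs of cross-parameter constraints. Ensembles are
reproducible given a seed; per-day 2.5/50/97.5% envelopes of arm length and
wet weight are returned.

Skill: MAE, MAPE (%) and RMSE over paired series; MAPE requires nonzero
observations; a fit is flagged good at MAPE ≤ 10%.

## Synthetic observations

The fixtures module generates observation tables with known truths so every
fit is testable closed-loop without external data: feeding rates at the
five mesocosm densities (5–48 mussels m⁻²); max-scaled metabolic rates at
the respirometry temperatures (10–26 °C), either from the full thermal
curve (for the grid search) or from a pure Arrhenius limb (the target of
the slope estimator); starvation weight series of ~100 g adults at 12 °C;
weight–length clouds from the cubic link; and a post-settlement ad-libitum
growth series at 14.5 °C over ~1.6 y. They emulate design, noise level and
truth ranges — not individual variability in feeding behavior, measurement
drift, or spawning-time stochasticity — so passing closed-loop tests shows
estimator correctness, not field accuracy.

## Problem sizes in the shipped tests

Test and benchmark runs use the smallest sizes that exercise the behavior:
lifecycle runs of ~300 d at `dt = 0.01/0.05`, six annual cycles for the
steady-cycle quantities, 100-d oracle comparisons, ensembles of a few dozen
draws, and event-ordering checks over 12–40 random parameter draws at
coarse `dt`.

## Known limitations

No pyloric-caecum compartment (the sea star's conventional storage organ;
its cyclic dynamics are better read as downstream of the DEB reserve), no
photoperiod-cued spawning (energetic criterion only, every 365 d), no
larval cloning or maternal egg-size effects, no aerial-exposure metabolic
depression, and no surface-area-linked maintenance. The thermal curve is
aquatic and untrustworthy above its ~295 K peak. Puberty timing is highly
sensitive to `E_H^p`, whose published value is uncertain (see above); the
simulated puberty weight (~54 g) sits ~19% below the reported ~67 g
benchmark under the shipped default, the one known systematic mismatch.
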