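"""Instantaneous DEB dynamics: fluxes, shape correction, state derivatives.

State variables of the standard DEB model with metabolic acceleration (abj):

* reserve E (J) — assimilated energy, mobilized before use;
* structure V (cm^3) — the permanent compartment paying volume-proportional
  somatic maintenance;
* maturity E_H (J) — cumulative investment in developmental complexity, with
  thresholds at birth (feeding onset), settlement/metamorphosis and puberty;
* reproductive buffer E_R (J) — post-puberty energy destined for gametes.

The kappa rule splits mobilized energy p_C: a fixed fraction kappa covers
somatic maintenance plus growth, the remainder maturity maintenance plus
maturation (immature) or reproduction (mature). Between birth and
metamorphosis, assimilation and conductance accelerate with the shape
correction M = L/L_b (exponential larval growth); M freezes at L_j/L_b
thereafter. During starvation, maintenance is charged at the reduced rate
p_M_starv and the unpaid demand is withdrawn from structure at the cost E_G
per cm^3 (shrinkage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .environment import EnvironmentAt
from .params import DEBParams, max_reserve_density

__all__ = [
    "OrganismState",
    "EnergyFluxes",
    "IntegrationFault",
    "shape_correction",
    "compute_fluxes",
    "state_derivative",
    "initial_embryo_state",
    "max_reserve_density",
]

#: Structural volume below which the organism is flagged dead (cm^3).
V_DEATH_FLOOR = 1e-12


class IntegrationFault(RuntimeError):
    """Non-finite flux or state encountered during integration."""


@dataclass(frozen=True)
class OrganismState:
    """Organism state at age t (d since fertilization).

    ``L_b_struct`` / ``L_j_struct`` record structural length (cm) at the
    birth and metamorphosis crossings; they are None until the corresponding
    maturity threshold has been reached.
    """

    t: float
    E: float
    V: float
    E_H: float
    E_R: float = 0.0
    L_b_struct: float | None = None
    L_j_struct: float | None = None

    def __post_init__(self) -> None:
        if not (self.V > 0):
            raise ValueError(f"structural volume must be positive, got {self.V}")
        if self.E < 0 or self.E_H < 0 or self.E_R < 0:
            raise ValueError(
                f"E, E_H, E_R must be non-negative, got {self.E}, {self.E_H}, {self.E_R}"
            )
        if self.L_b_struct is not None and self.L_j_struct is not None:
            if self.L_b_struct > self.L_j_struct:
                raise ValueError("structural length at birth exceeds that at metamorphosis")

    @property
    def L(self) -> float:
        """Structural length V^(1/3), cm."""
        return self.V ** (1.0 / 3.0)

    def scaled_reserve_density(self, params: DEBParams) -> float:
        """e = E / (V [E_m]), dimensionless."""
        return self.E / (self.V * max_reserve_density(params))

    def with_marks(self, params: DEBParams) -> "OrganismState":
        """Backfill missing stage marks for states constructed mid-life.

        Raises if E_H implies a stage whose mark is absent and cannot be
        inferred (a mark can only be backfilled when the state sits exactly
        at the crossing, i.e. for freshly constructed stage states).
        """
        st = self
        if st.E_H >= params.E_H_b and st.L_b_struct is None:
            raise ValueError("state past birth but L_b_struct unset")
        if st.E_H >= params.E_H_j and st.L_j_struct is None:
            raise ValueError("state past metamorphosis but L_j_struct unset")
        return st


@dataclass(frozen=True)
class EnergyFluxes:
    """Instantaneous energy fluxes, J d^-1."""

    p_A: float  # assimilation
    p_C: float  # mobilization
    p_S: float  # somatic maintenance (as charged)
    p_G: float  # growth (negative only while starving: shrinkage)
    p_J: float  # maturity maintenance
    p_R: float  # maturation (immature) or reproduction (mature)
    starving: bool


def shape_correction(
    L_struct: float,
    E_H: float,
    params: DEBParams,
    L_b_struct: float | None = None,
    L_j_struct: float | None = None,
) -> float:
    """Metabolic-acceleration factor M applied to p_Am and v.

    M = 1 for embryos (E_H < E_H_b), M = L/L_b during the larval phase,
    and M = L_j/L_b (frozen) after metamorphosis. Continuous at both
    transitions and non-decreasing along feasible trajectories.
    """
    if not (L_struct > 0):
        raise ValueError(f"structural length must be positive, got {L_struct}")
    if E_H < params.E_H_b:
        return 1.0
    if L_b_struct is None:
        raise ValueError("post-birth state requires the recorded length at birth")
    if E_H < params.E_H_j:
        return L_struct / L_b_struct
    if L_j_struct is None:
        raise ValueError("post-metamorphic state requires the recorded length at metamorphosis")
    return L_j_struct / L_b_struct


def _fluxes_raw(
    E: float,
    V: float,
    E_H: float,
    f: float,
    c: float,
    M: float,
    p: DEBParams,
) -> tuple[float, float, float, float, float, float, bool]:
    """Flux kernel on plain floats (hot path for the integrator).

    Returns (p_A, p_C, p_S, p_G, p_J, p_R, starving).
    """
    L2 = V ** (2.0 / 3.0)
    p_A = f * p.p_Am * c * M * L2 if E_H >= p.E_H_b else 0.0
    p_S_normal = p.p_M * c * V
    p_C = (E / V) * (p.E_G * p.v * c * M * L2 + p_S_normal) / (p.E_G + p.kappa * E / V)
    p_J = p.k_J * c * E_H
    kappa_p_C = p.kappa * p_C
    if kappa_p_C >= p_S_normal:
        p_S = p_S_normal
        p_G = kappa_p_C - p_S
        starving = False
    else:
        p_S = p.p_M_starv * c * V
        p_G = min(0.0, kappa_p_C - p_S)
        starving = True
    p_R = (1.0 - p.kappa) * p_C - p_J
    return p_A, p_C, p_S, p_G, p_J, p_R, starving


def compute_fluxes(
    state: OrganismState, env: EnvironmentAt, params: DEBParams
) -> EnergyFluxes:
    """Instantaneous fluxes for a state under a given environment.

    Embryos (E_H < E_H_b) do not assimilate. The starvation switch triggers
    when kappa p_C cannot cover the normal maintenance demand p_M c V; the
    charged maintenance then drops to p_M_starv c V and growth is clamped
    to non-positive (shrinkage).
    """
    M = shape_correction(
        state.L, state.E_H, params, state.L_b_struct, state.L_j_struct
    )
    vals = _fluxes_raw(
        state.E, state.V, state.E_H, env.f, env.c_T, M, params
    )
    if not all(math.isfinite(x) for x in vals[:6]):
        raise IntegrationFault(f"non-finite flux at state {state!r}: {vals}")
    return EnergyFluxes(*vals)


def _derivative_raw(
    E: float,
    V: float,
    E_H: float,
    E_R: float,
    f: float,
    c: float,
    M: float,
    p: DEBParams,
) -> tuple[float, float, float, float]:
    """(dE/dt, dV/dt, dE_H/dt, dE_R/dt) on plain floats."""
    p_A, p_C, p_S, p_G, p_J, p_R, _ = _fluxes_raw(E, V, E_H, f, c, M, p)
    dE = p_A - p_C
    dV = p_G / p.E_G
    if E_H < p.E_H_p:
        # maturation phase; maturity may decline when (1-kappa) p_C < p_J
        dE_H = p_R if (p_R >= 0.0 or E_H > 0.0) else 0.0
        dE_R = 0.0
    else:
        dE_H = 0.0
        if p_R >= 0.0 or E_R > 0.0:
            # reproduction, or deficit drawn from the buffer while it lasts
            dE_R = p_R
        else:
            # buffer exhausted: rejuvenation, maturity declines
            dE_R = 0.0
            dE_H = p_R
    return dE, dV, dE_H, dE_R


def state_derivative(
    state: OrganismState, env: EnvironmentAt, params: DEBParams
) -> tuple[float, float, float, float]:
    """Time derivatives (dE/dt, dV/dt, dE_H/dt, dE_R/dt).

    dE/dt = p_A - p_C; dV/dt = p_G / E_G (negative only while starving);
    maturation routes p_R to E_H below puberty and to E_R above it, with
    maturity-maintenance deficits paid from E_R before E_H declines.
    """
    M = shape_correction(
        state.L, state.E_H, params, state.L_b_struct, state.L_j_struct
    )
    d = _derivative_raw(
        state.E, state.V, state.E_H, state.E_R, env.f, env.c_T, M, params
    )
    if not all(math.isfinite(x) for x in d):
        raise IntegrationFault(f"non-finite derivative at state {state!r}: {d}")
    return d


#: Embryo initial structural length (cm); structure is essentially nil at
#: fertilization and the result is insensitive to this seed value.
EMBRYO_L0 = 1e-3

_E0_BRACKET = (1e-4, 1e2)
_BISECT_MAX_ITER = 60
_E_BIRTH_TOL = 1e-3


def _simulate_embryo_to_birth(
    E0: float, c: float, params: DEBParams, dt: float, t_max: float
) -> tuple[float, float, float, float] | None:
    """Integrate an embryo (M = 1, no feeding) until E_H crosses E_H_b.

    Returns (t_birth, E, V, E_H) at the crossing (linearly interpolated
    within the final step) or None if the threshold is never reached.
    """
    E, V, E_H = E0, EMBRYO_L0**3, 0.0
    t = 0.0
    p = params
    while t < t_max:
        prev = (E, V, E_H)
        # RK4 on (E, V, E_H); E_R stays 0 for embryos
        k1 = _derivative_raw(E, V, E_H, 0.0, 0.0, c, 1.0, p)
        k2 = _derivative_raw(E + dt / 2 * k1[0], V + dt / 2 * k1[1], E_H + dt / 2 * k1[2], 0.0, 0.0, c, 1.0, p)
        k3 = _derivative_raw(E + dt / 2 * k2[0], V + dt / 2 * k2[1], E_H + dt / 2 * k2[2], 0.0, 0.0, c, 1.0, p)
        k4 = _derivative_raw(E + dt * k3[0], V + dt * k3[1], E_H + dt * k3[2], 0.0, 0.0, c, 1.0, p)
        E += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        V += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        E_H += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        t += dt
        if E <= 0 or V <= 0:
            return None
        if E_H >= p.E_H_b:
            th = (p.E_H_b - prev[2]) / (E_H - prev[2])
            tb = t - dt + th * dt
            Eb = prev[0] + th * (E - prev[0])
            Vb = prev[1] + th * (V - prev[1])
            return tb, Eb, Vb, p.E_H_b
    return None


def initial_embryo_state(
    params: DEBParams,
    f_expected: float,
    c_T: float = 1.0,
    dt: float = 0.005,
    t_max: float = 200.0,
) -> OrganismState:
    """Embryo state at t = 0 under the maternal-matching rule.

    The egg's initial reserve E_0 is found by bisection so that the scaled
    reserve density e = E/(V [E_m]) at the moment maturity first reaches
    E_H_b equals ``f_expected`` — mothers provision eggs to match the food
    level they experience. ``c_T`` is the thermal correction of the
    incubation environment.
    """
    if not (0.0 < f_expected <= 1.0):
        raise ValueError(f"f_expected must lie in (0, 1], got {f_expected}")
    Em = max_reserve_density(params)

    def e_at_birth(E0: float) -> float | None:
        res = _simulate_embryo_to_birth(E0, c_T, params, dt, t_max)
        if res is None:
            return None
        _, Eb, Vb, _ = res
        return Eb / (Vb * Em)

    lo, hi = _E0_BRACKET
    e_lo, e_hi = e_at_birth(lo), e_at_birth(hi)
    # an egg too small never reaches birth: treat as e < target
    f_lo = -math.inf if e_lo is None else e_lo - f_expected
    f_hi = -math.inf if e_hi is None else e_hi - f_expected
    if f_hi < 0 or (f_lo > 0):
        raise ValueError(
            "embryo initialization infeasible: no sign change of e(birth) - f "
            f"over E0 in [{lo}, {hi}] J (e_lo={e_lo}, e_hi={e_hi})"
        )
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        e_mid = e_at_birth(mid)
        err = -math.inf if e_mid is None else e_mid - f_expected
        if abs(err) < _E_BIRTH_TOL / 10:
            lo = hi = mid
            break
        if err < 0:
            lo = mid
        else:
            hi = mid
    E0 = 0.5 * (lo + hi)
    return OrganismState(t=0.0, E=E0, V=EMBRYO_L0**3, E_H=0.0, E_R=0.0)
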