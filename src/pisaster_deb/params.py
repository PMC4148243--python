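"""DEB parameter set for *Pisaster ochraceus* and its sampling distribution.

The default parameter vector follows published estimates for this species
(covariation-method fits complemented by direct laboratory estimates of the
half-saturation prey density, starvation maintenance, Arrhenius slope and
post-metamorphic shape coefficient).

One default deviates from the commonly printed table: maturity at puberty
``E_H_p``. The printed magnitude (1.39e7 J, with a standard deviation seven
times its mean) delays puberty to roughly 3.8 years at ~1.5 kg wet weight,
which is incompatible with the reported ad-libitum life history of the
species as represented by this model (puberty at ~264 d and ~67 g). The
shipped default, 1.39e5 J, reproduces those landmarks and is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["DEBParams", "ParamDistribution", "default_params", "default_distribution"]


@dataclass(frozen=True)
class DEBParams:
    """Parameter vector of the full-lifecycle DEB model.

    Units: energies J, lengths cm, volumes cm^3, masses g, times d,
    temperatures K. Rates are per day.
    """

    X_K: float = 13.9          # half-saturation prey density, mussels m^-2
    p_Am: float = 43.2         # max surface-area-specific assimilation, J d^-1 cm^-2
    v: float = 0.04            # energy conductance, cm d^-1
    kappa: float = 0.58        # fraction of mobilized energy to soma
    p_M: float = 40.43         # volume-specific somatic maintenance, J d^-1 cm^-3
    p_M_starv: float = 11.5    # somatic maintenance during prolonged starvation
    E_G: float = 2743.0        # volume-specific cost of structure, J cm^-3
    E_H_b: float = 0.012       # maturity at birth (feeding onset), J
    E_H_j: float = 100.0       # maturity at settlement/metamorphosis, J
    E_H_p: float = 1.39e5      # maturity at puberty, J (see module docstring)
    delta_larv: float = 0.959  # larval shape coefficient
    delta_post: float = 0.52   # post-metamorphic shape coefficient
    k_J: float = 2.9e-6        # maturity-maintenance rate coefficient, d^-1
    T_A: float = 6000.0        # Arrhenius temperature, K
    T_L: float = 280.0         # lower bound of thermal tolerance range, K
    T_H: float = 297.0         # upper bound of thermal tolerance range, K
    T_AL: float = 31000.0      # Arrhenius temperature at the lower bound, K
    T_AH: float = 190000.0     # Arrhenius temperature at the upper bound, K
    T_ref: float = 293.0       # reference temperature, K
    d_V: float = 1.0           # density of structure, g cm^-3
    w_E: float = 4.35e-5       # weight-energy coupler for reserve/buffer, g J^-1
    W_E_mol: float = 23.9      # per-carbon molecular weight of reserve, g mol^-1
    mu_E: float = 550e3        # chemical potential of reserve, J mol^-1
    spawn_period: float = 365.0  # interval between spawnings, d

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "X_K", "p_Am", "v", "p_M", "p_M_starv", "E_G",
            "E_H_b", "E_H_j", "E_H_p", "delta_larv", "delta_post", "k_J",
            "T_A", "T_L", "T_H", "T_AL", "T_AH", "T_ref",
            "d_V", "w_E", "W_E_mol", "mu_E", "spawn_period",
        )
        for name in positive:
            val = getattr(self, name)
            if not (val > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {val!r}")
        if not (0.0 < self.kappa < 1.0):
            raise ValueError(f"kappa must lie in (0, 1), got {self.kappa!r}")
        if not (self.T_L < self.T_ref < self.T_H):
            raise ValueError(
                f"temperature bounds must satisfy T_L < T_ref < T_H, "
                f"got T_L={self.T_L}, T_ref={self.T_ref}, T_H={self.T_H}"
            )
        if not (self.E_H_b < self.E_H_j < self.E_H_p):
            raise ValueError(
                f"maturity thresholds must satisfy E_H_b < E_H_j < E_H_p, "
                f"got {self.E_H_b}, {self.E_H_j}, {self.E_H_p}"
            )
        if self.p_M_starv > self.p_M:
            raise ValueError(
                f"starvation maintenance p_M_starv={self.p_M_starv} exceeds p_M={self.p_M}"
            )
        # w_E is W_E_mol / mu_E by definition; allow 1% slack for rounded inputs
        implied = self.W_E_mol / self.mu_E
        if abs(self.w_E - implied) > 0.01 * implied:
            raise ValueError(
                f"w_E={self.w_E} inconsistent with W_E_mol/mu_E={implied:.4g} (>1% off)"
            )

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def replace(self, **changes: float) -> "DEBParams":
        """Return a validated copy with the given fields changed."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def max_reserve_density(params: DEBParams) -> float:
    """Volume-specific maximum reserve density [E_m] = p_Am / v, J cm^-3.

    Metabolic acceleration cancels: it multiplies p_Am and v identically.
    """
    return params.p_Am / params.v


# Published standard deviations for the estimated parameters. Parameters kept
# fixed (conversion constants, T_ref) and the grid-searched thermal-tolerance
# parameters carry no SD and default to zero here.
_DEFAULT_SD = {
    "X_K": 2.3,
    "p_Am": 4.1,
    "v": 0.01,
    "kappa": 0.07,
    "p_M": 1.41,
    "p_M_starv": 2.74,
    "E_G": 97.22,
    "E_H_b": 4.8e-4,
    "E_H_j": 4.21,
    "E_H_p": 99e6,
    "delta_larv": 144.56,
    "delta_post": 0.03,
    "k_J": 0.018,
    "T_A": 335.0,
}


@dataclass(frozen=True)
class ParamDistribution:
    """Independent per-parameter normal distributions around a DEBParams mean.

    ``sd`` maps parameter name -> standard deviation (same units as the
    parameter); parameters absent from the map are treated as fixed.
    ``policy`` controls how draws violating DEBParams invariants are handled:

    - ``"resample"``: redraw each offending parameter (counted); aborts if
      more than half of all attempted draws are infeasible.
    - ``"truncnorm"``: sample each parameter from the exact normal truncated
      to its feasible interval.
    """

    mean: DEBParams = field(default_factory=lambda: DEBParams())
    sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SD))
    policy: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.policy not in ("resample", "truncnorm"):
            raise ValueError(f"unknown truncation policy {self.policy!r}")
        unknown = set(self.sd) - set(DEBParams.field_names())
        if unknown:
            raise ValueError(f"SDs given for unknown parameters: {sorted(unknown)}")
        for name, s in self.sd.items():
            if s < 0:
                raise ValueError(f"negative SD for {name}: {s}")
        self.mean.validate()


def default_params() -> DEBParams:
    """The shipped default parameter vector (see module docstring)."""
    return DEBParams()


def default_distribution(policy: str = "truncnorm") -> ParamDistribution:
    return ParamDistribution(policy=policy)
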