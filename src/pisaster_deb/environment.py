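"""Environmental forcing: prey functional response and thermal correction.

Two transducers map the environment onto the DEB rates:

* a Holling Type II (saturating) functional response turning prey density X
  (mussels m^-2) into the scaled feeding level f = X / (X + X_K) in [0, 1];
* a five-parameter Arrhenius thermal performance curve, scaled so that its
  maximum over a fixed reference grid equals one, turning body temperature
  T (K) into a multiplicative rate correction c_T in (0, 1].

All physiological rates (p_Am, v, p_M, p_M_starv, k_J) are corrected by the
same c_T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .params import DEBParams

__all__ = [
    "EnvironmentAt",
    "ForcingSeries",
    "functional_response",
    "arrhenius_unscaled",
    "arrhenius_scaled",
    "thermal_correction_max",
    "env_at",
]

# Normalization grid for the scaled thermal curve; fixed so c_T is
# reproducible bit-for-bit across runs.
NORMALIZATION_GRID = (276.0, 302.0, 0.01)

# Aquatic thermal performance data do not constrain the curve above its peak
# (~295 K); simulations beyond it are allowed but flagged.
TPC_VALIDITY_MAX_K = 295.0

_T_SANITY = (270.0, 320.0)


@dataclass(frozen=True)
class EnvironmentAt:
    """Environmental state at one instant: T (K), X (mussels m^-2), f, c_T."""

    T: float
    X: float
    f: float
    c_T: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"scaled functional response f={self.f} outside [0, 1]")
        if not (self.c_T > 0):
            raise ValueError(f"thermal correction c_T={self.c_T} must be positive")
        if self.c_T > 1.0 + 1e-6:
            raise ValueError(f"c_T={self.c_T} exceeds 1 under max-normalization")


def functional_response(X: float, params: DEBParams) -> float:
    """Scaled Type II functional response f = X / (X + X_K)."""
    if X < 0:
        raise ValueError(f"prey density must be non-negative, got {X}")
    return X / (X + params.X_K)


def _arrhenius_unscaled_scalar(T: float, params: DEBParams) -> float:
    def s(T_: float) -> float:
        low = math.exp(params.T_AL / T_ - params.T_AL / params.T_L)
        try:
            high = math.exp(params.T_AH / params.T_H - params.T_AH / T_)
        except OverflowError:
            high = math.inf
        return 1.0 + low + high

    core = math.exp(params.T_A / params.T_ref - params.T_A / T)
    return core * s(params.T_ref) / s(T)


def arrhenius_unscaled(T, params: DEBParams):
    """Five-parameter Arrhenius correction relative to T_ref (unscaled).

    exp(T_A/T_ref - T_A/T) * s(T_ref)/s(T) with
    s(T) = 1 + exp(T_AL/T - T_AL/T_L) + exp(T_AH/T_H - T_AH/T).
    Equals 1 at T = T_ref by construction and is suppressed towards zero
    outside the tolerance range (T_L, T_H).
    """
    if np.ndim(T) == 0:
        if not T > 0:
            raise ValueError(f"absolute temperature must be positive, got {T}")
        return _arrhenius_unscaled_scalar(float(T), params)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    with np.errstate(over="ignore"):
        s = lambda T_: (
            1.0
            + np.exp(params.T_AL / T_ - params.T_AL / params.T_L)
            + np.exp(params.T_AH / params.T_H - params.T_AH / T_)
        )
        core = np.exp(params.T_A / params.T_ref - params.T_A / T)
        return core * s(params.T_ref) / s(T)


@lru_cache(maxsize=64)
def _normalization_max(thermal_key: tuple[float, ...]) -> float:
    T_A, T_L, T_H, T_AL, T_AH, T_ref, lo, hi, step = thermal_key
    params = DEBParams(T_A=T_A, T_L=T_L, T_H=T_H, T_AL=T_AL, T_AH=T_AH, T_ref=T_ref)
    grid = np.arange(lo, hi + step / 2, step)
    return float(np.max(arrhenius_unscaled(grid, params)))


def thermal_correction_max(
    params: DEBParams, grid: tuple[float, float, float] = NORMALIZATION_GRID
) -> float:
    """Maximum of the unscaled Arrhenius curve over the normalization grid."""
    lo, hi, step = grid
    if not (hi > lo and step > 0) or (hi - lo) / step < 2:
        raise ValueError(f"degenerate normalization grid {grid}")
    key = (
        params.T_A, params.T_L, params.T_H, params.T_AL, params.T_AH,
        params.T_ref, lo, hi, step,
    )
    return _normalization_max(key)


def arrhenius_scaled(
    T, params: DEBParams, grid: tuple[float, float, float] = NORMALIZATION_GRID
):
    """Scaled thermal correction c_T(T), max-normalized to 1 on ``grid``."""
    return arrhenius_unscaled(T, params) / thermal_correction_max(params, grid)


@dataclass(frozen=True)
class ForcingSeries:
    """Piecewise forcing of temperature and food.

    Breakpoints ``t`` (d, strictly increasing) carry temperature ``T`` (K)
    and either prey density ``X`` (mussels m^-2) or a direct override of the
    scaled functional response ``f``; an ``f`` value wins over ``X`` where
    both are present (NaN marks absence). Interpolation is piecewise-constant
    (daily model resolution) by default; ``interpolation="linear"`` is
    available for temperature and prey density.
    """

    t: np.ndarray
    T: np.ndarray
    X: np.ndarray | None = None
    f: np.ndarray | None = None
    interpolation: str = "previous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.atleast_1d(np.asarray(self.t, dtype=float)))
        object.__setattr__(self, "T", np.atleast_1d(np.asarray(self.T, dtype=float)))
        if self.X is not None:
            object.__setattr__(self, "X", np.atleast_1d(np.asarray(self.X, dtype=float)))
        if self.f is not None:
            object.__setattr__(self, "f", np.atleast_1d(np.asarray(self.f, dtype=float)))
        if self.t.size == 0:
            raise ValueError("empty forcing series")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("forcing breakpoints must be strictly increasing")
        if self.T.shape != self.t.shape:
            raise ValueError("temperature series must match breakpoints in length")
        lo, hi = _T_SANITY
        if np.any((self.T < lo) | (self.T > hi)):
            raise ValueError(f"temperatures outside the sanity band [{lo}, {hi}] K")
        if self.X is None and self.f is None:
            raise ValueError("forcing needs prey density X or functional response f")
        if self.X is not None:
            if self.X.shape != self.t.shape:
                raise ValueError("prey density series must match breakpoints in length")
            if np.any(self.X[~np.isnan(self.X)] < 0):
                raise ValueError("prey densities must be non-negative")
        if self.f is not None:
            if self.f.shape != self.t.shape:
                raise ValueError("f series must match breakpoints in length")
            ok = self.f[~np.isnan(self.f)]
            if np.any((ok < 0) | (ok > 1)):
                raise ValueError("f overrides must lie in [0, 1]")
        if self.interpolation not in ("previous", "linear"):
            raise ValueError(f"unknown interpolation mode {self.interpolation!r}")

    @classmethod
    def constant(
        cls, T: float, X: float | None = None, f: float | None = None
    ) -> "ForcingSeries":
        """Constant forcing (single breakpoint at t = 0)."""
        return cls(
            t=np.array([0.0]),
            T=np.array([float(T)]),
            X=None if X is None else np.array([float(X)]),
            f=None if f is None else np.array([float(f)]),
        )

    def _interp(self, series: np.ndarray, t: float) -> float:
        if self.t.size == 1:
            return float(series[0])
        if self.interpolation == "previous":
            idx = int(np.searchsorted(self.t, t, side="right")) - 1
            idx = min(max(idx, 0), self.t.size - 1)
            return float(series[idx])
        return float(np.interp(t, self.t, series))

    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


def env_at(t: float, forcing: ForcingSeries, params: DEBParams) -> EnvironmentAt:
    """Environment at time t: interpolate forcing and derive f and c_T.

    Times beyond the forcing span use constant extrapolation of the nearest
    breakpoint. Temperatures above the thermal curve's aquatic validity
    (~295 K) are simulated but trigger a warning.
    """
    T = forcing._interp(forcing.T, t)
    f_override = math.nan
    if forcing.f is not None:
        f_override = forcing._interp(forcing.f, t)
    X = math.nan
    if forcing.X is not None:
        X = forcing._interp(forcing.X, t)

    if not math.isnan(f_override):
        f = f_override
        if math.isnan(X):
            # implied prey density consistent with f (informational only)
            X = params.X_K * f / (1.0 - f) if f < 1.0 else math.inf
    elif not math.isnan(X):
        f = functional_response(X, params)
    else:
        raise ValueError(f"forcing provides neither f nor X at t={t}")

    if T > TPC_VALIDITY_MAX_K:
        warnings.warn(
            f"body temperature {T:.2f} K exceeds the aquatic thermal curve's "
            f"validity (~{TPC_VALIDITY_MAX_K:.0f} K); extrapolating",
            RuntimeWarning,
            stacklevel=2,
        )
    c_T = arrhenius_unscaled(T, params) / thermal_correction_max(params)
    return EnvironmentAt(T=T, X=X, f=f, c_T=min(c_T, 1.0))
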