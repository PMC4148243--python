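"""Synthetic observation generator for the calibration and validation fits.

Each fixture emulates one of the experimental designs behind the direct
parameter fits, with a known generating truth attached as metadata so the
closed loop fit(generate(spec)) can be tested without external data:

* ``feeding``  — scaled feeding rates at the five mesocosm prey densities
  (5, 11, 21, 32, 48 mussels m^-2), additive Gaussian noise;
* ``tpc``      — max-scaled metabolic rates at the respirometry temperatures
  (10, 14, 18, 20, 24, 26 degC), additive Gaussian noise;
* ``starvation`` — wet-weight series of ~100 g starved adults at 12 degC,
  weighed at irregular intervals, additive Gaussian noise;
* ``shape``    — arm length / wet weight pairs from the cubic structural
  link, multiplicative lognormal noise;
* ``growth``   — a post-settlement growth series (arm length and wet weight)
  at 14.5 degC and f = 1 over ~1.6 y, the rehearsal analogue of a long-term
  ad-libitum growth validation data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import ObservationTable
from .core import OrganismState
from .environment import ForcingSeries, arrhenius_scaled
from .params import DEBParams
from .simulate import adult_state, integrate, simulate_lifecycle

__all__ = ["FixtureSpec", "generate", "reference_stage_marks"]

_ROLES = ("feeding", "tpc", "starvation", "shape", "growth")

# experimental designs mirrored by the fixtures
FEEDING_DENSITIES = (5.0, 11.0, 21.0, 32.0, 48.0)  # mussels m^-2
TPC_TEMPS_K = (283.15, 287.15, 291.15, 293.15, 297.15, 299.15)  # 10..26 degC
STARVATION_T_K = 285.15       # 12 degC
STARVATION_W0_G = 100.0
GROWTH_T_K = 287.65           # 14.5 degC
GROWTH_DURATION_D = 584.0     # ~1.6 y


_MIN_DESIGN = {"feeding": 4, "tpc": 3, "starvation": 4, "shape": 10, "growth": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic observation set.

    ``truth`` overrides individual parameters of the generating model;
    ``noise_sd`` is the additive Gaussian sd on the response (multiplicative
    lognormal sigma for the shape role). ``design`` overrides the default
    design points; ``n_rep`` the replicates per point (feeding/tpc) or the
    number of individuals (starvation/shape).
    """

    role: str
    seed: int
    truth: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    design: tuple | None = None
    n_rep: int = 4

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown fixture role {self.role!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.design is not None and len(self.design) < _MIN_DESIGN[self.role]:
            raise ValueError(
                f"{self.role} design needs >= {_MIN_DESIGN[self.role]} points"
            )


_marks_cache: dict[tuple, tuple[float, float]] = {}


def reference_stage_marks(
    params: DEBParams, T: float = STARVATION_T_K, f: float = 1.0
) -> tuple[float, float]:
    """Structural lengths at birth and metamorphosis for a parameter set.

    Runs the embryo + larval phase once per (params, T, f) and caches the
    result; post-metamorphic fixtures and fits need these marks to fix the
    acceleration factor.
    """
    key = (tuple(sorted(params.as_dict().items())), T, f)
    if key not in _marks_cache:
        traj = simulate_lifecycle(params, T=T, f=f, t_end=250.0, dt=0.02, dt_post=0.1)
        if traj.L_b_struct is None or traj.L_j_struct is None:
            raise RuntimeError("lifecycle run did not reach metamorphosis")
        _marks_cache[key] = (traj.L_b_struct, traj.L_j_struct)
    return _marks_cache[key]


def _clip_resample(rng, draw, lo: float, n_max: int = 100):
    """Redraw values below ``lo``; floor at ``lo`` after n_max tries."""
    vals = draw()
    n_floored = 0
    for _ in range(n_max):
        bad = vals < lo
        if not np.any(bad):
            break
        vals = np.where(bad, draw(), vals)
    else:
        n_floored = int(np.sum(vals < lo))
        vals = np.maximum(vals, lo)
    return vals, n_floored


def generate(spec: FixtureSpec, params: DEBParams | None = None):
    """Generate one synthetic observation set (deterministic given seed).

    Returns an :class:`ObservationTable` (roles feeding/tpc/starvation/shape)
    or a tidy :class:`pandas.DataFrame` growth series (role growth). The
    generating truth is attached under ``meta['truth']``.
    """
    base = params if params is not None else DEBParams()
    rng = np.random.default_rng(spec.seed)
    if spec.role == "feeding":
        return _gen_feeding(spec, base, rng)
    if spec.role == "tpc":
        return _gen_tpc(spec, base, rng)
    if spec.role == "starvation":
        return _gen_starvation(spec, base, rng)
    if spec.role == "shape":
        return _gen_shape(spec, base, rng)
    return _gen_growth(spec, base, rng)


def _gen_feeding(spec: FixtureSpec, base: DEBParams, rng) -> ObservationTable:
    X_K = float(spec.truth.get("X_K", base.X_K))
    densities = np.asarray(spec.design if spec.design is not None else FEEDING_DENSITIES)
    X = np.repeat(densities, spec.n_rep)
    f_true = X / (X + X_K)
    y, n_floored = _clip_resample(
        rng, lambda: f_true + rng.normal(0.0, spec.noise_sd, X.size), 0.0
    )
    y = np.minimum(y, 1.2)
    return ObservationTable(
        role="feeding", predictor=X, response=y,
        meta={"truth": {"X_K": X_K}, "noise_sd": spec.noise_sd, "seed": spec.seed,
              "n_floored": n_floored},
    )


def _gen_tpc(spec: FixtureSpec, base: DEBParams, rng) -> ObservationTable:
    truth = {
        k: float(spec.truth.get(k, getattr(base, k)))
        for k in ("T_A", "T_L", "T_H", "T_AL", "T_AH")
    }
    cand = base.replace(**truth)
    temps = np.asarray(spec.design if spec.design is not None else TPC_TEMPS_K)
    T = np.repeat(temps, spec.n_rep)
    form = spec.truth.get("tpc_form", "full")
    if form == "arrhenius":
        # pure Arrhenius limb (no tolerance-range suppression): the target of
        # the slope-based T_A estimator
        raw = np.exp(-truth["T_A"] / T)
        rate_true = raw / raw.max()
    elif form == "full":
        rate_true = arrhenius_scaled(T, cand)
    else:
        raise ValueError(f"unknown tpc_form {form!r}")
    y, n_floored = _clip_resample(
        rng, lambda: rate_true + rng.normal(0.0, spec.noise_sd, T.size), 1e-6
    )
    y = np.minimum(y, 1.2)
    return ObservationTable(
        role="tpc", predictor=T, response=y,
        meta={"truth": truth, "noise_sd": spec.noise_sd, "seed": spec.seed,
              "n_floored": n_floored},
    )


def _gen_starvation(spec: FixtureSpec, base: DEBParams, rng) -> ObservationTable:
    n_ind = spec.n_rep
    lo, hi = spec.truth.get("p_M_starv_range", (8.0, 15.0))
    truths = rng.uniform(lo, hi, n_ind)
    if "p_M_starv" in spec.truth:
        truths = np.full(n_ind, float(spec.truth["p_M_starv"]))
    days = np.asarray(
        spec.design if spec.design is not None
        else (0.0, 21.0, 49.0, 91.0, 140.0, 203.0, 280.0, 364.0, 467.0)
    )
    marks = reference_stage_marks(base)
    frames = []
    for i, pms in enumerate(truths):
        cand = base.replace(p_M_starv=float(min(pms, base.p_M)))
        init = adult_state(cand, STARVATION_W0_G, *marks, e=1.0)
        forcing = ForcingSeries.constant(T=STARVATION_T_K, f=0.0)
        traj = integrate(cand, forcing, (0.0, float(days.max())), init, dt=0.25, dt_post=0.25)
        W = np.interp(days, traj.t, traj.wet_weight)
        W_obs, _ = _clip_resample(
            rng, lambda: W + rng.normal(0.0, spec.noise_sd, W.size), 1e-3
        )
        W_obs[0] = W[0]  # initial weighing defines the simulation start
        frames.append(
            pd.DataFrame({"individual": f"ind{i + 1}", "time_d": days, "wet_weight_g": W_obs})
        )
    df = pd.concat(frames, ignore_index=True)
    return ObservationTable(
        role="starvation",
        predictor=df["time_d"].to_numpy(),
        response=df["wet_weight_g"].to_numpy(),
        individual=df["individual"].to_numpy(),
        meta={
            "truth": {"p_M_starv": truths.tolist()},
            "noise_sd": spec.noise_sd, "seed": spec.seed,
            "T": STARVATION_T_K, "marks": marks,
        },
    )


def _gen_shape(spec: FixtureSpec, base: DEBParams, rng) -> ObservationTable:
    delta = float(spec.truth.get("delta_post", 0.59))
    n = spec.n_rep if spec.n_rep >= 10 else 457
    L = rng.uniform(2.0, 18.0, n)
    W = (delta * L) ** 3 * np.exp(rng.normal(0.0, spec.noise_sd, n))
    return ObservationTable(
        role="shape", predictor=L, response=W,
        meta={"truth": {"delta_post": delta}, "noise_sd": spec.noise_sd, "seed": spec.seed},
    )


def _gen_growth(spec: FixtureSpec, base: DEBParams, rng) -> pd.DataFrame:
    """Post-settlement ad-libitum growth series at 14.5 degC (~1.6 y)."""
    truth = {k: float(v) for k, v in spec.truth.items()}
    cand = base.replace(**truth) if truth else base
    marks = reference_stage_marks(cand)
    days = np.asarray(
        spec.design if spec.design is not None
        else np.linspace(0.0, GROWTH_DURATION_D, 25)
    )
    # start at settlement: maturity at the threshold so puberty is crossed
    # during the series, as in a juvenile cohort followed from settlement
    V0 = marks[1] ** 3
    Em = cand.p_Am / cand.v
    init = OrganismState(
        t=0.0, E=V0 * Em, V=V0, E_H=cand.E_H_j, E_R=0.0,
        L_b_struct=marks[0], L_j_struct=marks[1],
    )
    forcing = ForcingSeries.constant(T=GROWTH_T_K, f=1.0)
    traj = integrate(cand, forcing, (0.0, float(days.max())), init, dt=0.1, dt_post=0.1)
    arm = np.interp(days, traj.t, traj.physical_length)
    W = np.interp(days, traj.t, traj.wet_weight)
    arm_obs, _ = _clip_resample(rng, lambda: arm + rng.normal(0.0, spec.noise_sd, arm.size), 1e-3)
    W_obs, _ = _clip_resample(rng, lambda: W * np.exp(rng.normal(0.0, spec.noise_sd, W.size)), 1e-3)
    df = pd.DataFrame(
        {"time_d": days, "arm_length_cm": arm_obs, "wet_weight_g": W_obs}
    )
    df.attrs["truth"] = truth or cand.as_dict()
    df.attrs["seed"] = spec.seed
    df.attrs["T"] = GROWTH_T_K
    return df
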