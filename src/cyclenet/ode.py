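"""Five-gene nonlinear ODE system for cell cycle regulators.

The expression levels x1..x5 of CCNB1, TP53, CCND1, CDKN1B and CDH1
evolve under a coupled system that is linear except for one bilinear
term (r24 * x1 * x3, the CCNB1-CCND1 product driving the TP53 equation):

    dx1/dt = r11 x1 + r12 x2 + r13 x5
    dx2/dt = r21 x1 + r22 x2 + r23 x3 + r24 x1 x3
    dx3/dt = r31 x2 + r32 x3 + r33 x4 + r34 x5
    dx4/dt = r41 x1 + r42 x3 + r43 x4 + r44 x5
    dx5/dt = r51 x2 + r52 x3 + r53 x4 + r54 x5

The 19 rate coefficients r_ij are estimated from random-walk sample
trajectories (see :mod:`cyclenet.calibration`).  Integration uses the
classical fixed-step fourth-order Runge-Kutta scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .randomwalk import StateTrajectory

__all__ = [
    "GENE_VARIABLES",
    "PARAM_NAMES",
    "ODEParameters",
    "DivergenceError",
    "SteadyStateResult",
    "rhs",
    "simulate_rk4",
    "steady_state",
]

# x1..x5 in equation order.  The mapping is data, not hard-coded into the
# maths, so an alternative gene ordering can be carried alongside.
GENE_VARIABLES: tuple[str, ...] = ("CCNB1", "TP53", "CCND1", "CDKN1B", "CDH1")

PARAM_NAMES: tuple[str, ...] = (
    "r11", "r12", "r13",
    "r21", "r22", "r23", "r24",
    "r31", "r32", "r33", "r34",
    "r41", "r42", "r43", "r44",
    "r51", "r52", "r53", "r54",
)


class DivergenceError(RuntimeError):
    """The integration produced a non-finite state."""

    def __init__(self, time: float):
        super().__init__(f"trajectory diverged (non-finite state) at t = {time:g}")
        self.time = time


@dataclass(frozen=True)
class ODEParameters:
    """The 19 rate coefficients of the five-gene system."""

    r11: float
    r12: float
    r13: float
    r21: float
    r22: float
    r23: float
    r24: float
    r31: float
    r32: float
    r33: float
    r34: float
    r41: float
    r42: float
    r43: float
    r44: float
    r51: float
    r52: float
    r53: float
    r54: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ODEParameters":
        missing = set(PARAM_NAMES) - set(mapping)
        extra = set(mapping) - set(PARAM_NAMES)
        if missing or extra:
            raise KeyError(
                f"parameter map must have exactly the 19 r_ij keys "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES})

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ODEParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (19,):
            raise ValueError(f"expected 19 values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])


def rhs(x: np.ndarray, params: ODEParameters) -> np.ndarray:
    """Time derivative (dx1..dx5)/dt at state ``x``.

    Linear in the parameters for fixed x — the property the static
    (gradient-matching) calibration stage exploits.
    """
    x1, x2, x3, x4, x5 = np.asarray(x, dtype=float)
    p = params
    return np.array(
        [
            p.r11 * x1 + p.r12 * x2 + p.r13 * x5,
            p.r21 * x1 + p.r22 * x2 + p.r23 * x3 + p.r24 * x1 * x3,
            p.r31 * x2 + p.r32 * x3 + p.r33 * x4 + p.r34 * x5,
            p.r41 * x1 + p.r42 * x3 + p.r43 * x4 + p.r44 * x5,
            p.r51 * x2 + p.r52 * x3 + p.r53 * x4 + p.r54 * x5,
        ]
    )


def _integrate(
    params: ODEParameters,
    x0,
    h: float,
    t_end: float,
    record: bool,
    stop_tol: float | None = None,
    clamp: float | None = None,
):
    """Shared fixed-step RK4 driver (scalar arithmetic for speed).

    Returns (times, states, converged).  If ``stop_tol`` is given the
    loop additionally stops once the max-norm of the derivative falls
    below it, reporting converged=True.
    """
    p = params
    r11, r12, r13 = p.r11, p.r12, p.r13
    r21, r22, r23, r24 = p.r21, p.r22, p.r23, p.r24
    r31, r32, r33, r34 = p.r31, p.r32, p.r33, p.r34
    r41, r42, r43, r44 = p.r41, p.r42, p.r43, p.r44
    r51, r52, r53, r54 = p.r51, p.r52, p.r53, p.r54

    def f(x1, x2, x3, x4, x5):
        return (
            r11 * x1 + r12 * x2 + r13 * x5,
            r21 * x1 + r22 * x2 + r23 * x3 + r24 * x1 * x3,
            r31 * x2 + r32 * x3 + r33 * x4 + r34 * x5,
            r41 * x1 + r42 * x3 + r43 * x4 + r44 * x5,
            r51 * x2 + r52 * x3 + r53 * x4 + r54 * x5,
        )

    x1, x2, x3, x4, x5 = (float(v) for v in x0)
    t = 0.0
    times = [0.0]
    states = [(x1, x2, x3, x4, x5)]
    converged = False

    if stop_tol is not None:
        d = f(x1, x2, x3, x4, x5)
        if max(abs(v) for v in d) < stop_tol:
            return times, states, True

    while t < t_end - 1e-12:
        step = min(h, t_end - t)  # final partial step lands exactly on t_end
        k11, k12, k13, k14, k15 = f(x1, x2, x3, x4, x5)
        hh = 0.5 * step
        k21, k22, k23, k24, k25 = f(
            x1 + hh * k11, x2 + hh * k12, x3 + hh * k13, x4 + hh * k14, x5 + hh * k15
        )
        k31, k32, k33, k34, k35 = f(
            x1 + hh * k21, x2 + hh * k22, x3 + hh * k23, x4 + hh * k24, x5 + hh * k25
        )
        k41, k42, k43, k44, k45 = f(
            x1 + step * k31, x2 + step * k32, x3 + step * k33, x4 + step * k34, x5 + step * k35
        )
        s = step / 6.0
        x1 += s * (k11 + 2 * k21 + 2 * k31 + k41)
        x2 += s * (k12 + 2 * k22 + 2 * k32 + k42)
        x3 += s * (k13 + 2 * k23 + 2 * k33 + k43)
        x4 += s * (k14 + 2 * k24 + 2 * k34 + k44)
        x5 += s * (k15 + 2 * k25 + 2 * k35 + k45)
        t += step
        if clamp is not None:
            # saturate instead of diverging: keeps least-squares objectives
            # finite when a trial parameter set is unstable
            x1 = min(max(x1, -clamp), clamp)
            x2 = min(max(x2, -clamp), clamp)
            x3 = min(max(x3, -clamp), clamp)
            x4 = min(max(x4, -clamp), clamp)
            x5 = min(max(x5, -clamp), clamp)
        if not (
            math.isfinite(x1) and math.isfinite(x2) and math.isfinite(x3)
            and math.isfinite(x4) and math.isfinite(x5)
        ):
            raise DivergenceError(t)
        if record:
            times.append(t)
            states.append((x1, x2, x3, x4, x5))
        else:
            times[0] = t
            states[0] = (x1, x2, x3, x4, x5)
        if stop_tol is not None:
            d = f(x1, x2, x3, x4, x5)
            if max(abs(v) for v in d) < stop_tol:
                converged = True
                break
    return times, states, converged


def simulate_rk4(
    params: ODEParameters,
    x0,
    h: float = 0.01,
    t_end: float = 60.0,
    clamp: float | None = None,
) -> StateTrajectory:
    """Integrate the system with classical RK4 at fixed step ``h``.

    The trajectory is sampled at every step from t = 0 to ``t_end``;
    the final step is shortened to land exactly on ``t_end``.  With
    ``clamp`` set, state components saturate at ±clamp instead of
    raising :class:`DivergenceError` — used by the calibration stage to
    keep its objective finite on unstable trial parameter sets.
    """
    if h <= 0:
        raise ValueError("step size h must be positive")
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    times, states, _ = _integrate(params, x0, h, t_end, record=True, clamp=clamp)
    return StateTrajectory(
        times=np.array(times), states=np.array(states), labels=GENE_VARIABLES
    )


@dataclass(frozen=True)
class SteadyStateResult:
    """Terminal state of a steady-state search."""

    state: np.ndarray
    converged: bool
    time: float


def steady_state(
    params: ODEParameters,
    x0,
    h: float = 0.01,
    tol: float = 1e-8,
    t_max: float = 500.0,
) -> SteadyStateResult:
    """Integrate until the derivative max-norm drops below ``tol``.

    Returns the final state with a converged flag; the flag is False if
    ``t_max`` is reached first.
    """
    if h <= 0:
        raise ValueError("step size h must be positive")
    times, states, converged = _integrate(
        params, x0, h, t_max, record=False, stop_tol=tol
    )
    return SteadyStateResult(
        state=np.array(states[-1]), converged=converged, time=times[-1]
    )
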