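"""Two-compartment subcutaneous insulin absorption model.

Insulin delivered by pump (basal infusion plus prandial boluses) enters a
first subcutaneous compartment and cascades into a second one, both draining
with first-order rate constant 1/t_max, where t_max is the time-to-peak
plasma concentration in minutes:

    dQ1/dt = Inf(t) + Bol(t) - Q1/t_max
    dQ2/dt = (Q1 - Q2)/t_max,        Q1(0) = Q2(0) = 0

with Q1, Q2 insulin masses in mU and t = 0 at midnight of day 1, so that the
states at the start of the observation window are determined by the dosing
record alone.  Plasma concentration equilibrates instantaneously with the
efflux from compartment 2 and carries a linear "residual insulin" drift:

    mu(theta, z, t) = conv * Q2(t) / (t_max * wt * MCR) + a*(t - t_end) + b

where wt is body weight (kg), MCR the metabolic clearance rate (l/kg/min),
t_end the 5 h post-meal reference time and conv the mU -> pmol conversion
(default 6.0, i.e. 1 U = 6 nmol).  Observations are Gaussian around mu with
variance kappa^2 + lambda^2 * mu^2, combining additive and multiplicative
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels

__all__ = [
    "KineticParams",
    "DosingSchedule",
    "CompartmentState",
    "ProfileContext",
    "NuisanceParams",
    "IntegrationFailure",
    "DegenerateVarianceError",
    "input_rate",
    "integrate_compartments",
    "closed_form_compartments",
    "predicted_concentration",
    "log_likelihood",
    "q2_at",
    "ode_call_count",
    "reset_ode_call_count",
]

DEFAULT_UNIT_CONVERSION = 6.0  # pmol per mU
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-6  # mU

# instrumentation: number of times the numerical integrator has been launched
_ODE_CALLS = [0]


def ode_call_count() -> int:
    """Number of numerical integrator launches since the last reset."""
    return _ODE_CALLS[0]


def reset_ode_call_count() -> None:
    _ODE_CALLS[0] = 0


def _count_ode_call() -> None:
    _ODE_CALLS[0] += 1


class IntegrationFailure(RuntimeError):
    """Raised when the adaptive integrator cannot advance (non-finite state
    or step-size underflow)."""

    def __init__(self, message: str, profile_id: str | None = None):
        super().__init__(message if profile_id is None
                         else f"profile {profile_id}: {message}")
        self.profile_id = profile_id


class DegenerateVarianceError(ValueError):
    """Raised when the observation variance kappa^2 + lambda^2 mu^2 is zero."""


@dataclass(frozen=True)
class KineticParams:
    """Profile-level kinetic parameter vector theta = (t_max, MCR, a, b).

    t_max: time-to-peak insulin concentration, minutes (> 0).
    mcr: metabolic clearance rate, l/kg/min (> 0).
    a: residual-insulin accumulation rate, pmol/l/min.
    b: post-prandial residual concentration at t_end, pmol/l.
    """

    t_max: float
    mcr: float
    a: float
    b: float

    def __post_init__(self):
        if not self.t_max > 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if not self.mcr > 0:
            raise ValueError(f"MCR must be positive, got {self.mcr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_max, self.mcr, self.a, self.b])


@dataclass(frozen=True)
class NuisanceParams:
    """Residual-error parameters: additive sd kappa (pmol/l) in [0, 100] and
    multiplicative coefficient lambda (dimensionless) in [0, 1]."""

    kappa: float
    lam: float

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 100.0:
            raise ValueError(f"kappa must be in [0, 100], got {self.kappa}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


@dataclass(frozen=True)
class CompartmentState:
    """Insulin masses (mU) in the two subcutaneous compartments at time t."""

    q1: float
    q2: float
    t: float


@dataclass(frozen=True)
class ProfileContext:
    """Observed per-profile data entering the regression function."""

    wt: float  # body weight, kg
    t_end: float  # 5 h post-meal reference time, minutes
    t_start: float = 0.0  # trial start time, minutes
    unit_conversion: float = DEFAULT_UNIT_CONVERSION  # pmol per mU

    def __post_init__(self):
        if not self.wt > 0:
            raise ValueError(f"weight must be positive, got {self.wt}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")


@dataclass(frozen=True)
class DosingSchedule:
    """Exogenous insulin input: basal infusion segments and bolus events.

    basal_segments: (start_min, end_min, rate_mU_per_min) tuples, pairwise
    non-overlapping.  bolus_events: (start_min, duration_min, dose_mU); each
    bolus is a square pulse of the stated duration (1 min by convention for
    standard prandial boluses).
    """

    basal_segments: tuple[tuple[float, float, float], ...] = ()
    bolus_events: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        segs = tuple(tuple(map(float, s)) for s in self.basal_segments)
        bols = tuple(tuple(map(float, e)) for e in self.bolus_events)
        object.__setattr__(self, "basal_segments", segs)
        object.__setattr__(self, "bolus_events", bols)
        for s, e, _r in segs:
            if not (0 <= s < e):
                raise ValueError(f"invalid basal segment [{s}, {e})")
        for i, (s1, e1, _) in enumerate(segs):
            for s2, e2, _ in segs[i + 1:]:
                if s1 < e2 and s2 < e1:
                    raise ValueError("basal segments overlap")
        for s, d, dose in bols:
            if s < 0 or d <= 0:
                raise ValueError(f"invalid bolus (start={s}, duration={d})")
            if dose < 0:
                raise ValueError("bolus dose must be non-negative")

    def piecewise_rates(self, t_stop: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant total input rate covering [0, t_stop].

        Returns (breakpoints, rates): rate[i] applies on
        [breakpoints[i], breakpoints[i+1]).
        """
        cuts = {0.0, float(t_stop)}
        for s, e, _ in self.basal_segments:
            cuts.add(s)
            cuts.add(e)
        for s, d, _ in self.bolus_events:
            cuts.add(s)
            cuts.add(s + d)
        brk = np.array(sorted(c for c in cuts if c <= t_stop))
        if brk[-1] < t_stop:
            brk = np.append(brk, t_stop)
        rates = np.array([input_rate(0.5 * (lo + hi), self)
                          for lo, hi in zip(brk[:-1], brk[1:])])
        return brk, rates


def input_rate(t: float, dosing: DosingSchedule) -> float:
    """Total insulin input rate Inf(t) + Bol(t) in mU/min.

    Piecewise constant and right-continuous: a segment or bolus starting at t
    is already active at t; one ending at t is not.
    """
    r = 0.0
    for s, e, rate in dosing.basal_segments:
        if s <= t < e:
            r += rate
    for s, d, dose in dosing.bolus_events:
        if s <= t < s + d:
            r += dose / d
    return r


def q2_at(
    dosing: DosingSchedule,
    t_max: float,
    out_times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    profile_id: str | None = None,
) -> np.ndarray:
    """Compartment-2 mass (mU) at the given sorted times (fast path)."""
    out_times = np.asarray(out_times, dtype=float)
    _count_ode_call()
    brk, rates = dosing.piecewise_rates(float(out_times[-1]) if len(out_times) else 0.0)
    _q1, q2, status = _kernels.integrate_piecewise(brk, rates, t_max, out_times, rtol, atol)
    if status != 0:
        raise IntegrationFailure(
            f"integrator failed (status {status}) at t_max={t_max}", profile_id
        )
    return q2


def integrate_compartments(
    dosing: DosingSchedule,
    t_max: float,
    out_times: Sequence[float],
    tol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    profile_id: str | None = None,
) -> list[CompartmentState]:
    """Solve the absorption cascade with the adaptive Cash-Karp 4(5) pair.

    Integration always starts from Q1 = Q2 = 0 at t = 0; every dosing
    discontinuity and every output time is a forced step boundary so the
    embedded error estimate is never taken across a jump in the input rate.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    out_times = np.asarray(out_times, dtype=float)
    if len(out_times) and (np.any(np.diff(out_times) < 0) or out_times[0] < 0):
        raise ValueError("out_times must be sorted and non-negative")
    _count_ode_call()
    brk, rates = dosing.piecewise_rates(float(out_times[-1]) if len(out_times) else 0.0)
    q1, q2, status = _kernels.integrate_piecewise(brk, rates, t_max, out_times, tol, atol)
    if status != 0:
        raise IntegrationFailure(
            f"integrator failed (status {status}) at t_max={t_max}", profile_id
        )
    return [CompartmentState(q1=float(a), q2=float(b), t=float(t))
            for a, b, t in zip(q1, q2, out_times)]


def closed_form_compartments(
    dosing: DosingSchedule, t_max: float, t: float
) -> CompartmentState:
    """Exact analytic state of the linear cascade at time t.

    The input is piecewise constant, so (Q1, Q2) propagate in closed form
    across each constant-rate segment:

        Q1(s) = rT + (Q1_0 - rT) e^{-s/T}
        Q2(s) = rT + e^{-s/T} [ Q2_0 - rT + (Q1_0 - rT) s/T ]

    with T = t_max and s time since the segment start.  Intended as an
    independent oracle for the numerical integrator.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    T = float(t_max)
    brk, rates = dosing.piecewise_rates(float(t))
    q1 = 0.0
    q2 = 0.0
    for lo, hi, r in zip(brk[:-1], brk[1:], rates):
        if lo >= t:
            break
        s = min(hi, t) - lo
        rT = r * T
        e = math.exp(-s / T)
        q1_new = rT + (q1 - rT) * e
        q2_new = rT + e * (q2 - rT + (q1 - rT) * s / T)
        q1, q2 = q1_new, q2_new
    return CompartmentState(q1=q1, q2=q2, t=float(t))


def predicted_concentration(
    params: KineticParams,
    ctx: ProfileContext,
    t: np.ndarray | float,
    q2: np.ndarray | float,
) -> np.ndarray | float:
    """Regression function mu in pmol/l; q2 must come from the same t_max."""
    return (
        ctx.unit_conversion * np.asarray(q2) / (params.t_max * ctx.wt * params.mcr)
        + params.a * (np.asarray(t) - ctx.t_end)
        + params.b
    )


def log_likelihood(
    times: np.ndarray,
    concentrations: np.ndarray,
    params: KineticParams,
    nuis: NuisanceParams,
    ctx: ProfileContext,
    dosing: DosingSchedule,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Profile log-likelihood under the heteroscedastic observation model."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if len(y) == 0:
        raise ValueError("at least one observation is required")
    q2 = q2_at(dosing, params.t_max, times, rtol=rtol, atol=atol)
    mu = predicted_concentration(params, ctx, times, q2)
    var = nuis.kappa**2 + nuis.lam**2 * mu**2
    if np.any(var <= 0):
        raise DegenerateVarianceError(
            "observation variance is zero (kappa = 0 and lambda*mu = 0)"
        )
    return float(np.sum(-0.5 * np.log(2 * np.pi * var) - 0.5 * (y - mu) ** 2 / var))
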