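"""Closed-form compartmental kinetics for zero-order (infusion) input.

One- and two-compartment disposition with first-order elimination, solved
analytically per dose event and combined by superposition (the kinetics are
linear). Units are fixed package-wide: time in hours, volumes in litres,
clearances in L/h; dose amounts are entered in mg and converted internally to
micrograms so that concentrations come out in ``µg/L``, which is numerically
identical to ng/mL.

The module exposes a scalar, user-facing API (:func:`concentration_2cmt`,
:func:`exposure_metrics`, ...) plus vectorised kernels (``_conc2_batch``)
used by the estimation engine, which evaluates many subjects at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DoseEvent",
    "PKParameters",
    "ConcentrationProfile",
    "ExposureMetrics",
    "macro_constants",
    "concentration_2cmt",
    "concentration_1cmt",
    "auc_exact",
    "auc_trapezoid",
    "exposure_metrics",
]

MG_TO_UG = 1000.0

#: relative guard separating the two disposition eigenvalues; see methods note
_EIGEN_SEP = 1e-10


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion: ``amount`` mg delivered over ``duration`` h
    starting at ``start_time`` h."""

    amount: float
    start_time: float = 0.0
    duration: float = 0.75

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0 mg, got {self.amount}")
        if self.start_time < 0:
            raise ValueError("dose start_time must be >= 0 h")
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0 h")

    @property
    def rate_ug_per_h(self) -> float:
        return self.amount * MG_TO_UG / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class PKParameters:
    """Individual two-compartment parameters.

    V : central volume (L); Vp : peripheral volume (L);
    CL : elimination clearance from the central compartment (L/h);
    CLp : inter-compartmental clearance (L/h).
    """

    V: float
    Vp: float
    CL: float
    CLp: float

    def __post_init__(self) -> None:
        for name in ("V", "Vp", "CL", "CLp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")

    @property
    def k10(self) -> float:
        return self.CL / self.V

    @property
    def k12(self) -> float:
        return self.CLp / self.V

    @property
    def k21(self) -> float:
        return self.CLp / self.Vp


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have the same shape")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class ExposureMetrics:
    Cmax: float        # ng/mL
    Tmax: float        # h
    AUC_0_t: float     # µg·h/L
    AUC_0_inf: float   # µg·h/L


def _validate_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _sorted_regimen(regimen: Iterable[DoseEvent]) -> list[DoseEvent]:
    events = list(regimen)
    return sorted(events, key=lambda e: e.start_time)


def macro_constants(params: PKParameters) -> tuple[float, float]:
    """Disposition exponents (alpha, beta) of the two-compartment model.

    They are the eigenvalue magnitudes of the micro-rate matrix and satisfy
    ``alpha + beta = k10 + k12 + k21`` and ``alpha * beta = k10 * k21`` with
    ``alpha >= beta > 0``.
    """
    a, b = _macro_arrays(
        np.asarray(params.V), np.asarray(params.Vp),
        np.asarray(params.CL), np.asarray(params.CLp),
    )
    return float(a), float(b)


def _macro_arrays(V, Vp, CL, CLp):
    """Vectorised (alpha, beta) with a guard against a repeated eigenvalue."""
    k10 = CL / V
    k12 = CLp / V
    k21 = CLp / Vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    # repeated-root guard: keep the exponents numerically distinct
    disc = np.maximum(disc, _EIGEN_SEP * s)
    alpha = 0.5 * (s + disc)
    # floor beta away from 0 (k10*k21 -> 0 limit) so 1/beta stays finite
    beta = np.maximum(0.5 * (s - disc), 1e-14 * s)
    return alpha, beta


# ---------------------------------------------------------------------------
# batched kernels (used by the NLME engine); shapes:
#   parameters (..., 1, 1) broadcast against times (..., T, 1) and doses (..., 1, D)
# ---------------------------------------------------------------------------

def _conc2_batch(V, Vp, CL, CLp, times, amt_ug, start, dur, dose_mask):
    """Two-compartment infusion concentrations, fully vectorised.

    Parameters are arrays broadcastable to ``(N,)``; ``times`` is ``(N, T)``;
    dose arrays are ``(N, D)`` with ``dose_mask`` flagging real events.
    Returns concentrations ``(N, T)`` in µg/L.
    """
    V = np.asarray(V, dtype=float)[..., None, None]
    Vp = np.asarray(Vp, dtype=float)[..., None, None]
    CL = np.asarray(CL, dtype=float)[..., None, None]
    CLp = np.asarray(CLp, dtype=float)[..., None, None]
    alpha, beta = _macro_arrays(V, Vp, CL, CLp)
    k21 = CLp / Vp
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)

    t = np.asarray(times, dtype=float)[..., :, None]      # (N, T, 1)
    s = np.asarray(start, dtype=float)[..., None, :]       # (N, 1, D)
    d = np.asarray(dur, dtype=float)[..., None, :]
    rate = np.asarray(amt_ug, dtype=float)[..., None, :] / d
    m = np.asarray(dose_mask, dtype=bool)[..., None, :]

    def running(x):
        # concentration of a never-ending infusion of unit-normalised rate
        x = np.maximum(x, 0.0)
        return (A / alpha * (-np.expm1(-alpha * x))
                + B / beta * (-np.expm1(-beta * x)))

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        contrib = rate / V * (running(t - s) - running(t - s - d))
        return np.sum(np.where(m, contrib, 0.0), axis=-1)


def _conc1_batch(V, CL, times, amt_ug, start, dur, dose_mask):
    """One-compartment analogue of :func:`_conc2_batch`."""
    V = np.asarray(V, dtype=float)[..., None, None]
    CL = np.asarray(CL, dtype=float)[..., None, None]
    k = CL / V

    t = np.asarray(times, dtype=float)[..., :, None]
    s = np.asarray(start, dtype=float)[..., None, :]
    d = np.asarray(dur, dtype=float)[..., None, :]
    rate = np.asarray(amt_ug, dtype=float)[..., None, :] / d
    m = np.asarray(dose_mask, dtype=bool)[..., None, :]

    def running(x):
        x = np.maximum(x, 0.0)
        return -np.expm1(-k * x) / k

    contrib = rate / V * (running(t - s) - running(t - s - d))
    return np.sum(np.where(m, contrib, 0.0), axis=-1)


try:  # jitted mask-aware kernels for the estimation hot path
    import math

    from numba import njit

    @njit(cache=True, fastmath=True, error_model="numpy")
    def _conc2_masked(V, Vp, CL, CLp, times, obs_mask, amt, start, dur,
                      dose_mask, out):
        M, T = times.shape
        D = amt.shape[1]
        for i in range(M):
            k10 = CL[i] / V[i]
            k12 = CLp[i] / V[i]
            k21 = CLp[i] / Vp[i]
            s = k10 + k12 + k21
            disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
            if disc < 1e-10 * s:
                disc = 1e-10 * s
            al = 0.5 * (s + disc)
            be = 0.5 * (s - disc)
            if be < 1e-14 * s:
                be = 1e-14 * s
            A = (al - k21) / (al - be)
            B = (k21 - be) / (al - be)
            for j in range(T):
                if not obs_mask[i, j]:
                    out[i, j] = 0.0
                    continue
                acc = 0.0
                t = times[i, j]
                for d in range(D):
                    if not dose_mask[i, d]:
                        continue
                    x1 = t - start[i, d]
                    if x1 <= 0.0:
                        continue
                    x2 = x1 - dur[i, d]
                    rate = amt[i, d] / dur[i, d]
                    e1a = -math.expm1(-al * x1)
                    e1b = -math.expm1(-be * x1)
                    if x2 > 0.0:
                        e2a = -math.expm1(-al * x2)
                        e2b = -math.expm1(-be * x2)
                    else:
                        e2a = 0.0
                        e2b = 0.0
                    acc += rate / V[i] * (A / al * (e1a - e2a)
                                          + B / be * (e1b - e2b))
                out[i, j] = acc
        return out

    @njit(cache=True, fastmath=True, error_model="numpy")
    def _conc1_masked(V, CL, times, obs_mask, amt, start, dur, dose_mask,
                      out):
        M, T = times.shape
        D = amt.shape[1]
        for i in range(M):
            k = CL[i] / V[i]
            for j in range(T):
                if not obs_mask[i, j]:
                    out[i, j] = 0.0
                    continue
                acc = 0.0
                t = times[i, j]
                for d in range(D):
                    if not dose_mask[i, d]:
                        continue
                    x1 = t - start[i, d]
                    if x1 <= 0.0:
                        continue
                    x2 = x1 - dur[i, d]
                    rate = amt[i, d] / dur[i, d]
                    e1 = -math.expm1(-k * x1)
                    e2 = -math.expm1(-k * x2) if x2 > 0.0 else 0.0
                    acc += rate / V[i] * (e1 - e2) / k
                out[i, j] = acc
        return out

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False
    _conc2_masked = _conc1_masked = None


def _regimen_arrays(regimen: Sequence[DoseEvent]):
    if len(regimen) == 0:
        return (np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)),
                np.zeros((1, 1), dtype=bool))
    ev = _sorted_regimen(regimen)
    amt = np.array([[e.amount * MG_TO_UG for e in ev]])
    start = np.array([[e.start_time for e in ev]])
    dur = np.array([[e.duration for e in ev]])
    mask = np.ones_like(amt, dtype=bool)
    return amt, start, dur, mask


def concentration_2cmt(params: PKParameters, regimen: Sequence[DoseEvent],
                       times) -> ConcentrationProfile:
    """Concentration–time profile of a two-compartment model under an
    arbitrary infusion regimen, by superposition of per-event closed forms."""
    t = _validate_times(times)
    amt, start, dur, mask = _regimen_arrays(regimen)
    c = _conc2_batch(np.array([params.V]), np.array([params.Vp]),
                     np.array([params.CL]), np.array([params.CLp]),
                     t[None, :], amt, start, dur, mask)[0]
    return ConcentrationProfile(t, c)


def concentration_1cmt(params_1cmt: tuple[float, float],
                       regimen: Sequence[DoseEvent], times) -> ConcentrationProfile:
    """One-compartment profile; ``params_1cmt`` is ``(V, CL)``."""
    V, CL = params_1cmt
    if V <= 0 or CL <= 0:
        raise ValueError("V and CL must be strictly positive")
    t = _validate_times(times)
    amt, start, dur, mask = _regimen_arrays(regimen)
    c = _conc1_batch(np.array([V]), np.array([CL]),
                     t[None, :], amt, start, dur, mask)[0]
    return ConcentrationProfile(t, c)


# ---------------------------------------------------------------------------
# exposure metrics
# ---------------------------------------------------------------------------

def _auc_running_2cmt(params: PKParameters, x: float) -> float:
    """Integral 0..x of the unit-rate never-ending-infusion concentration."""
    if x <= 0:
        return 0.0
    alpha, beta = macro_constants(params)
    k21 = params.k21
    A = (alpha - k21) / (alpha - beta)
    B = (k21 - beta) / (alpha - beta)
    return (A / alpha * (x - (-np.expm1(-alpha * x)) / alpha)
            + B / beta * (x - (-np.expm1(-beta * x)) / beta)) / params.V


def auc_exact(params: PKParameters, regimen: Sequence[DoseEvent], t_end: float) -> float:
    """AUC from 0 to ``t_end`` by the piecewise-analytic antiderivative of the
    closed form (µg·h/L). Exact up to floating point; no quadrature grid."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    total = 0.0
    for e in _sorted_regimen(regimen):
        rate = e.rate_ug_per_h
        total += rate * (_auc_running_2cmt(params, t_end - e.start_time)
                         - _auc_running_2cmt(params, t_end - e.end_time))
    return total


def auc_trapezoid(params: PKParameters, regimen: Sequence[DoseEvent], times) -> float:
    """Linear-trapezoid AUC on an explicit sampling schedule — the
    non-compartmental alternative to :func:`auc_exact`."""
    prof = concentration_2cmt(params, regimen, times)
    return float(np.trapezoid(prof.concentrations, prof.times))


def exposure_metrics(params: PKParameters, regimen: Sequence[DoseEvent],
                     t_end: float = 24.0, n_grid: int = 2001,
                     n_refine: int = 401) -> ExposureMetrics:
    """Cmax/Tmax and AUCs for a regimen.

    Cmax is located from analytic candidates (each infusion end, where the
    concentration of a single infusion peaks) plus a refined local grid around
    each candidate and a coarse global grid — multi-dose accumulation can move
    the global maximum to a later infusion. AUC_0_t uses the exact piecewise
    integral; AUC_0_inf is ``total dose / CL`` (linear kinetics).
    """
    events = _sorted_regimen(regimen)
    if not events:
        raise ValueError("exposure metrics need at least one dose event")
    last_end = max(e.end_time for e in events)
    if t_end <= last_end:
        raise ValueError(f"t_end={t_end} must exceed the last infusion end ({last_end})")

    candidates = [np.linspace(0.0, t_end, n_grid)]
    for e in events:
        w = e.duration
        lo = max(e.start_time, e.end_time - w)
        hi = min(t_end, e.end_time + w)
        candidates.append(np.linspace(lo, hi, n_refine))
        candidates.append(np.array([e.end_time]))
    grid = np.unique(np.concatenate(candidates))
    prof = concentration_2cmt(params, events, grid)
    i = int(np.argmax(prof.concentrations))
    cmax, tmax = float(prof.concentrations[i]), float(grid[i])

    auc_t = auc_exact(params, events, t_end)
    total_ug = sum(e.amount for e in events) * MG_TO_UG
    auc_inf = total_ug / params.CL
    return ExposureMetrics(Cmax=cmax, Tmax=tmax, AUC_0_t=auc_t, AUC_0_inf=auc_inf)
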