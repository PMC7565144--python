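"""Numerical integration of the hierarchy through a treatment schedule.

Treatments enter the model in exactly two ways, mirroring how therapy is
usually represented in compartmental tumor models:

* **windowed rate modifiers** -- a rate constant is multiplied (or
  replaced) over a half-open time window ``[start, end)``, e.g. a
  CSC-directed drug as a 100-fold elevation of the CSC death rate k6;
* **instantaneous kill events** -- at one time point a fraction of each
  compartment is removed at once, e.g. nonselective cytotoxic therapy as
  a 99% bulk kill; dead cells are assumed to be resorbed immediately.

Between breakpoints (window edges and event times) the rate constants are
constant and the ODE system is integrated numerically with an adaptive
solver; the integration is restarted exactly at every breakpoint so that
discontinuities are never smoothed across.  With an empty schedule the
result agrees with the analytic solution in :mod:`csclineage.model` to
integrator tolerance, which is the package's primary correctness check.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    CELLS_PER_MM3,
    PopulationState,
    growth_exponents,
    volume_mm3,
)
from .params import RATE_NAMES, RateConstants

__all__ = [
    "RateModifier",
    "KillEvent",
    "TreatmentSchedule",
    "Trajectory",
    "simulate",
    "apply_kill",
    "relapse_time",
    "growth_delay",
    "integrate_to_equilibrium",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RateModifier:
    """Modify one rate constant over the half-open window [start, end).

    Exactly one of ``factor`` (multiplies the baseline value) or
    ``replace`` (absolute replacement value) must be given.  Overlapping
    factor modifiers on the same rate compose multiplicatively; factors
    always multiply the baseline (or replacement), never each other's
    output.
    """

    target: str
    start: float
    end: float
    factor: float | None = None
    replace: float | None = None

    def __post_init__(self) -> None:
        if self.target not in RATE_NAMES:
            raise ValueError(f"unknown rate constant {self.target!r}; expected one of {RATE_NAMES}")
        if not self.start < self.end:
            raise ValueError(f"modifier window requires start < end, got [{self.start}, {self.end})")
        if (self.factor is None) == (self.replace is None):
            raise ValueError("exactly one of factor or replace must be set")
        if self.factor is not None and self.factor <= 0:
            raise ValueError(f"factor must be > 0, got {self.factor}")
        if self.replace is not None and self.replace < 0:
            raise ValueError(f"replacement rate must be >= 0, got {self.replace}")

    def active(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclasses.dataclass(frozen=True)
class KillEvent:
    """Instantaneous removal of a fraction of each compartment at time t."""

    t: float
    f_csc: float
    f_p: float
    f_d: float

    def __post_init__(self) -> None:
        for name in ("f_csc", "f_p", "f_d"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f_csc, self.f_p, self.f_d)


@dataclasses.dataclass(frozen=True)
class TreatmentSchedule:
    """An ordered collection of rate modifiers and kill events."""

    modifiers: tuple[RateModifier, ...] = ()
    events: tuple[KillEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        events = tuple(sorted(self.events, key=lambda e: e.t))
        times = [e.t for e in events]
        if len(set(times)) != len(times):
            raise ValueError("kill events must have strictly increasing times")
        object.__setattr__(self, "events", events)

    @property
    def empty(self) -> bool:
        return not self.modifiers and not self.events

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Schedule discontinuities strictly inside (t0, t1)."""
        pts = set()
        for m in self.modifiers:
            pts.update((m.start, m.end))
        pts.update(e.t for e in self.events)
        return sorted(p for p in pts if t0 < p < t1)

    def first_breakpoint(self) -> float | None:
        pts = [m.start for m in self.modifiers] + [e.t for e in self.events]
        return min(pts) if pts else None

    def rates_at(self, t: float, base: RateConstants) -> RateConstants:
        """Effective rate constants at time t (windows half-open)."""
        values = base.to_dict()
        active = [m for m in self.modifiers if m.active(t)]
        for name in RATE_NAMES:
            here = [m for m in active if m.target == name]
            if not here:
                continue
            replacements = [m.replace for m in here if m.replace is not None]
            if len(replacements) > 1:
                raise ValueError(f"overlapping replacement modifiers on {name} at t={t}")
            value = replacements[0] if replacements else values[name]
            for m in here:
                if m.factor is not None:
                    value *= m.factor
            values[name] = value
        return RateConstants.from_dict(values)

    def events_at(self, t: float, tol: float = 1e-9) -> list[KillEvent]:
        return [e for e in self.events if abs(e.t - t) <= tol]


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Time-gridded solution with derived totals, volume, and fractions.

    At a kill-event time the stored state is the post-kill state; the
    pre-kill value is the preceding grid point.
    """

    times: np.ndarray
    csc: np.ndarray
    p: np.ndarray
    d: np.ndarray
    treatment_breakpoints: tuple[float, ...] = ()
    density: float = CELLS_PER_MM3

    def __post_init__(self) -> None:
        for name in ("times", "csc", "p", "d"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.csc) == len(self.p) == len(self.d)):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n(self) -> np.ndarray:
        return self.csc + self.p + self.d

    @property
    def volume(self) -> np.ndarray:
        return self.n / self.density

    @property
    def frac_csc(self) -> np.ndarray:
        return _safe_fraction(self.csc, self.n)

    @property
    def frac_p(self) -> np.ndarray:
        return _safe_fraction(self.p, self.n)

    def state_at(self, index: int) -> PopulationState:
        return PopulationState(
            t=float(self.times[index]),
            csc=float(self.csc[index]),
            p=float(self.p[index]),
            d=float(self.d[index]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.times,
                "csc": self.csc,
                "p": self.p,
                "d": self.d,
                "n": self.n,
                "volume_mm3": self.volume,
                "frac_csc": self.frac_csc,
                "frac_p": self.frac_p,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, density: float = CELLS_PER_MM3) -> "Trajectory":
        required = {"day", "csc", "p", "d"}
        if not required <= set(frame.columns):
            raise ValueError(f"trajectory frame requires columns {sorted(required)}")
        return cls(
            times=frame["day"].to_numpy(),
            csc=frame["csc"].to_numpy(),
            p=frame["p"].to_numpy(),
            d=frame["d"].to_numpy(),
            density=density,
        )

    @classmethod
    def read_csv(cls, path, density: float = CELLS_PER_MM3) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path), density=density)


def _safe_fraction(part: np.ndarray, total: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, part / np.where(total > 0, total, 1.0), 0.0)
    return frac


def apply_kill(
    state: PopulationState, fractions: Sequence[float]
) -> PopulationState:
    """Scale each compartment by (1 - fraction); exact, no integrator."""
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(not 0.0 <= x <= 1.0 for x in f):
        raise ValueError(f"kill fractions must be three values in [0, 1], got {fractions!r}")
    return PopulationState(
        t=state.t,
        csc=state.csc * (1.0 - f[0]),
        p=state.p * (1.0 - f[1]),
        d=state.d * (1.0 - f[2]),
    )


def _clamp_negative(y: np.ndarray, scale: float) -> np.ndarray:
    """Zero tiny negative counts from integrator drift; larger ones are bugs."""
    floor = -1e-9 * max(scale, 1.0)
    if np.any(y < floor):
        raise RuntimeError(f"integrator produced a significantly negative state: {y}")
    if np.any(y < 0):
        logger.debug("clamping tiny negative counts to zero: %s", y)
    return np.maximum(y, 0.0)


def simulate(
    k: RateConstants,
    init: PopulationState,
    schedule: TreatmentSchedule | None = None,
    *,
    t_end: float,
    grid_step: float = 0.5,
    t_eval_extra: Iterable[float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
    extinction_threshold: float = 0.0,
    density: float = CELLS_PER_MM3,
) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end`` through a schedule.

    Parameters
    ----------
    extinction_threshold:
        Compartments that fall below this many cells at a schedule
        breakpoint are set to zero (a sub-single-cell deterministic
        population is biologically extinct).  The default 0 disables the
        rule and keeps the pure ODE semantics.
    t_eval_extra:
        Additional times to include in the output grid, e.g. observation
        days of a dataset being fitted.
    """
    if schedule is None:
        schedule = TreatmentSchedule()
    if t_end <= init.t:
        raise ValueError("t_end must exceed init.t")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")

    breakpoints = schedule.breakpoints(init.t, t_end)
    grid = np.arange(init.t, t_end, grid_step)
    extra = np.asarray(list(t_eval_extra), dtype=float) if t_eval_extra is not None else np.array([])
    if extra.size and (extra.min() < init.t or extra.max() > t_end):
        raise ValueError("t_eval_extra must lie within [init.t, t_end]")
    grid = np.unique(np.concatenate([grid, [t_end], breakpoints, extra]))

    seg_edges = [init.t] + breakpoints + [t_end]
    y = init.as_array()
    for event in schedule.events_at(init.t):
        y = y * (1.0 - np.asarray(event.fractions))
    times_out = [init.t]
    states_out = [y.copy()]
    for lo, hi in zip(seg_edges[:-1], seg_edges[1:]):
        rates = schedule.rates_at(0.5 * (lo + hi), k)
        a, bexp, c = growth_exponents(rates)
        alpha = rates.k2 + 2.0 * rates.k3
        two_k5 = 2.0 * rates.k5

        def rhs(t, yv):
            return [
                a * yv[0],
                alpha * yv[0] + bexp * yv[1],
                two_k5 * yv[1] + c * yv[2],
            ]

        def jac(t, yv):
            return [[a, 0.0, 0.0], [alpha, bexp, 0.0], [0.0, two_k5, c]]

        t_eval = grid[(grid > lo) & (grid <= hi)]
        if t_eval.size == 0 or t_eval[-1] != hi:
            t_eval = np.append(t_eval, hi)
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac=jac if method in ("LSODA", "BDF", "Radau") else None,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{lo}, {hi}]: {sol.message}")
        seg_y = sol.y.T
        scale = float(np.max(np.abs(seg_y))) if seg_y.size else 1.0
        seg_y = np.vstack([_clamp_negative(row, scale) for row in seg_y])
        times_out.extend(sol.t.tolist())
        states_out.extend(list(seg_y))
        y = seg_y[-1].copy()
        # breakpoint handling: kill events, then the extinction rule
        for event in schedule.events_at(hi):
            y = y * (1.0 - np.asarray(event.fractions))
            logger.info("kill event at day %.6g: fractions %s", hi, event.fractions)
        if extinction_threshold > 0:
            extinct = (y > 0) & (y < extinction_threshold)
            if np.any(extinct):
                logger.info(
                    "extinction at day %.6g: compartments %s below %.3g cells set to 0",
                    hi,
                    np.nonzero(extinct)[0].tolist(),
                    extinction_threshold,
                )
                y = np.where(extinct, 0.0, y)
        states_out[-1] = y.copy()

    times_arr = np.asarray(times_out)
    states_arr = np.vstack(states_out)
    first = schedule.first_breakpoint()
    bkpts: tuple[float, ...] = ()
    if first is not None:
        bkpts = tuple(sorted({first, *breakpoints}))

    return Trajectory(
        times=times_arr,
        csc=states_arr[:, 0],
        p=states_arr[:, 1],
        d=states_arr[:, 2],
        treatment_breakpoints=bkpts,
        density=density,
    )


def relapse_time(
    traj: Trajectory, reference_volume: float | None = None
) -> float | None:
    """First day after treatment begins at which the tumor regains volume.

    Relapse is operationalized as the volume re-attaining its value at
    treatment start (or an explicit ``reference_volume``) with positive
    slope.  Returns None for an untreated trajectory (with a warning) and
    for trajectories that never regain the reference.
    """
    if not traj.treatment_breakpoints:
        warnings.warn("relapse_time called on an untreated trajectory", stacklevel=2)
        return None
    t_start = min(traj.treatment_breakpoints)
    volume = traj.volume
    if reference_volume is None:
        # pre-treatment burden: the stored state *at* an event time is
        # post-kill, so read the last grid point strictly before the start
        before = np.nonzero(traj.times < t_start)[0]
        if before.size == 0:
            raise ValueError("trajectory has no points before treatment start")
        reference_volume = float(volume[before[-1]])
    if reference_volume <= 0:
        raise ValueError("reference_volume must be > 0")
    after = traj.times > t_start
    idx = np.nonzero(after)[0]
    dv = np.gradient(volume, traj.times)
    below_seen = False
    for i in idx:
        if volume[i] < reference_volume:
            below_seen = True
        elif below_seen and volume[i] >= reference_volume and dv[i] > 0:
            return float(traj.times[i])
    return None


def _first_crossing(traj: Trajectory, threshold: float) -> float | None:
    v = traj.volume
    above = np.nonzero(v >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))


def growth_delay(
    treated: Trajectory, control: Trajectory, threshold_volume: float
) -> float | None:
    """Delay (days) of the treated first crossing of a volume threshold.

    Linear interpolation between grid points; None when either trajectory
    never crosses the threshold.
    """
    if threshold_volume <= 0:
        raise ValueError("threshold_volume must be > 0")
    t_treated = _first_crossing(treated, threshold_volume)
    t_control = _first_crossing(control, threshold_volume)
    if t_treated is None or t_control is None:
        return None
    return t_treated - t_control


def integrate_to_equilibrium(
    k: RateConstants,
    f0: Sequence[float] | None = None,
    *,
    tol: float = 1e-12,
    max_days: float = 1e6,
    chunk_days: float = 500.0,
    rtol: float = 1e-12,
) -> tuple[float, float, float]:
    """Integrate the compartment-*fraction* dynamics until stationary.

    The fraction vector f = (CSC, P, D)/N obeys the normalized ODE
    ``df/dt = J f - (1' J f) f``; integrating it (rather than the raw
    counts) keeps the state bounded, so equilibrium can be reached even
    when absolute counts would overflow at k1 = 1.  Returns the settled
    (fCSC, fP, fD); stops when the max fraction drift rate falls below
    ``tol`` per day.  This is the simulation-based cross-check of
    :func:`csclineage.model.asymptotic_fractions`.
    """
    a, b, c = growth_exponents(k)
    alpha = k.k2 + 2.0 * k.k3
    two_k5 = 2.0 * k.k5

    def jf(f):
        return np.array(
            [a * f[0], alpha * f[0] + b * f[1], two_k5 * f[1] + c * f[2]]
        )

    def rhs(t, f):
        g = jf(f)
        return g - g.sum() * f

    f = np.array([1 / 3, 1 / 3, 1 / 3]) if f0 is None else np.asarray(f0, dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("f0 must be a nonnegative vector with positive sum")
    f = f / f.sum()
    elapsed = 0.0
    while elapsed < max_days:
        sol = solve_ivp(rhs, (0.0, chunk_days), f, method="LSODA", rtol=rtol, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"fraction integration failed: {sol.message}")
        f = np.maximum(sol.y[:, -1], 0.0)
        f = f / f.sum()
        elapsed += chunk_days
        if np.max(np.abs(rhs(0.0, f))) < tol:
            return float(f[0]), float(f[1]), float(f[2])
    raise RuntimeError(
        f"compartment fractions did not settle within {max_days} days "
        "(near-degenerate growth exponents?)"
    )
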