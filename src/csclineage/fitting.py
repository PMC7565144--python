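"""Calibration of the hierarchy model to tumor-volume growth curves.

Only the overall time scale of the model is free once the ratio space is
fixed: with the Phi ratios held constant, every rate constant is
proportional to k1, so fitting a growth curve reduces to a 1-D search over
k1 (optionally with a free initial-count scale).  Treatment multipliers
(e.g. how much a drug elevates a death rate) are likewise fitted by a 1-D
search with everything else held at the control fit.  Both searches use
bracketed derivative-free minimization with a deterministic bracket
derived from the data's crude doubling time, so a fit is reproducible from
its inputs alone.

The least-squares objective is on volumes by default (late, large
measurements dominate, matching how exponential growth curves are usually
fitted by eye); a log-volume objective is available as a switch.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import (
    CELLS_PER_MM3,
    ConstraintReport,
    PopulationState,
    asymptotic_fractions,
    check_constraints,
    closed_form_series,
    growth_exponents,
)
from .params import PhiRatios, RateConstants, phi_to_rates
from .simulate import TreatmentSchedule, RateModifier, simulate

__all__ = [
    "TumorDataset",
    "FitResult",
    "r_squared",
    "initial_state",
    "fit_growth",
    "fit_treatment",
    "constrained_phi_search",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TumorDataset:
    """Observed (day, volume mm^3) pairs plus initial-condition metadata."""

    days: np.ndarray
    volumes: np.ndarray
    initial_total_cells: float
    initial_frac_csc: float
    label: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        if days.shape != volumes.shape or days.ndim != 1:
            raise ValueError("days and volumes must be 1-D arrays of equal length")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(volumes <= 0):
            raise ValueError("volumes must be > 0")
        if self.initial_total_cells <= 0:
            raise ValueError("initial_total_cells must be > 0")
        if not 0.0 <= self.initial_frac_csc <= 1.0:
            raise ValueError("initial_frac_csc must be in [0, 1]")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", volumes)

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "volume_mm3": self.volumes})

    def write(self, path: str | pathlib.Path) -> None:
        """Write observations as CSV with a JSON metadata sidecar."""
        path = pathlib.Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "initial_total_cells": self.initial_total_cells,
            "initial_frac_csc": self.initial_frac_csc,
            "label": self.label,
        }
        if self.ground_truth is not None:
            meta["ground_truth"] = self.ground_truth
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, path: str | pathlib.Path) -> "TumorDataset":
        path = pathlib.Path(path)
        frame = pd.read_csv(path)
        if not {"day", "volume_mm3"} <= set(frame.columns):
            raise ValueError(f"{path}: expected columns day, volume_mm3")
        meta_path = path.with_suffix(".meta.json")
        if not meta_path.exists():
            raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
        meta = json.loads(meta_path.read_text())
        return cls(
            days=frame["day"].to_numpy(),
            volumes=frame["volume_mm3"].to_numpy(),
            initial_total_cells=float(meta["initial_total_cells"]),
            initial_frac_csc=float(meta["initial_frac_csc"]),
            label=str(meta.get("label", "")),
            ground_truth=meta.get("ground_truth"),
        )


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of a 1-D calibration."""

    params: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    converged: bool
    objective: float
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "r_squared": self.r_squared,
            "residuals": np.asarray(self.residuals).tolist(),
            "converged": self.converged,
            "objective": self.objective,
            "message": self.message,
        }


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    SS_tot is taken about the observed mean; a constant observed series is
    rejected because R^2 is then undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length 1-D series (n >= 2)")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series is constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def initial_state(
    total_cells: float,
    frac_csc: float,
    k: RateConstants,
    split_policy: str = "asymptotic",
    t0: float = 0.0,
) -> PopulationState:
    """Build the initial compartment split from total cells and CSC fraction.

    Experiments report only the inoculum size and its CSC fraction; the
    P:D split of the non-CSC remainder is a modelling choice:

    * ``"asymptotic"`` (default): non-CSC cells divided in the P:D ratio of
      the dominant growth mode for the given rates;
    * ``"all_p"``: the whole non-CSC remainder starts as progenitors;
    * ``"all_d"``: the whole remainder starts terminally differentiated.
    """
    csc = total_cells * frac_csc
    rest = total_cells - csc
    if split_policy == "asymptotic":
        mode = asymptotic_fractions(k)
        denom = mode.f_p + mode.f_d
        share_p = mode.f_p / denom if denom > 0 else 0.0
    elif split_policy == "all_p":
        share_p = 1.0
    elif split_policy == "all_d":
        share_p = 0.0
    else:
        raise ValueError(f"unknown split_policy {split_policy!r}")
    return PopulationState(t=t0, csc=csc, p=rest * share_p, d=rest * (1.0 - share_p))


def _doubling_time_bracket(data: TumorDataset, phi: PhiRatios) -> tuple[float, float, float]:
    """Deterministic k1 bracket from the data's crude exponential slope."""
    v0, v1 = data.volumes[0], data.volumes[-1]
    dt = data.days[-1] - data.days[0]
    slope = np.log(v1 / v0) / dt if v1 > v0 and dt > 0 else 0.0
    a_coeff = 1.0 - phi.phi_3_1 - phi.phi_6_1  # exponent per unit k1 (CSC-led)
    b_coeff = phi.phi_4_1 * (1.0 - phi.phi_5_4) - phi.phi_7_1  # P-led alternative
    lead = max(a_coeff, b_coeff)
    guess = slope / lead if slope > 0 and lead > 0 else 0.05
    guess = max(guess, 1e-6)
    return guess / 20.0, guess, guess * 20.0


def _predict_volumes(
    k: RateConstants,
    init: PopulationState,
    days: np.ndarray,
    schedule: TreatmentSchedule | None,
    density: float,
) -> np.ndarray:
    if schedule is None or schedule.empty:
        csc, p, d = closed_form_series(k, init, days)
        return (csc + p + d) / density
    t_end = float(days[-1])
    traj = simulate(
        k, init, schedule, t_end=t_end, grid_step=1.0, t_eval_extra=days
    )
    return np.interp(days, traj.times, traj.volume)


def _finish_fit(
    data: TumorDataset,
    predicted: np.ndarray,
    params: dict[str, float],
    objective: float,
    converged: bool,
    message: str,
) -> FitResult:
    residuals = data.volumes - predicted
    return FitResult(
        params=params,
        r_squared=r_squared(data.volumes, predicted),
        residuals=residuals,
        converged=converged,
        objective=objective,
        message=message,
    )


def fit_growth(
    data: TumorDataset,
    phi: PhiRatios,
    *,
    split_policy: str = "asymptotic",
    fit_scale: bool = False,
    log_objective: bool = False,
    density: float = CELLS_PER_MM3,
) -> FitResult:
    """Fit the time scale k1 of an untreated growth curve, Phi fixed.

    When ``fit_scale`` is set, a multiplicative initial-count scale is
    profiled out analytically at each candidate k1 (volume measurements
    and inoculum counts then need not share a calibration).
    """
    if len(data) < 3:
        raise ValueError("fit_growth requires at least 3 observations")
    lo, guess, hi = _doubling_time_bracket(data, phi)
    obs = np.log(data.volumes) if log_objective else data.volumes

    def model_volumes(k1: float) -> np.ndarray:
        k = phi_to_rates(phi, k1)
        init = initial_state(
            data.initial_total_cells, data.initial_frac_csc, k, split_policy, t0=0.0
        )
        return _predict_volumes(k, init, data.days, None, density)

    def objective(k1: float) -> float:
        pred = model_volumes(k1)
        if fit_scale:
            if log_objective:
                # optimal log-scale shift in closed form
                shift = float(np.mean(obs - np.log(np.maximum(pred, 1e-300))))
                return float(np.sum((obs - (np.log(np.maximum(pred, 1e-300)) + shift)) ** 2))
            denom = float(np.dot(pred, pred))
            s = float(np.dot(pred, data.volumes)) / denom if denom > 0 else 1.0
            return float(np.sum((data.volumes - s * pred) ** 2))
        series = np.log(np.maximum(pred, 1e-300)) if log_objective else pred
        return float(np.sum((obs - series) ** 2))

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12 * guess}
    )
    k1_hat = float(res.x)
    at_edge = (k1_hat - lo) < 1e-6 * guess or (hi - k1_hat) < 1e-6 * guess
    converged = bool(res.success) and not at_edge
    message = "" if converged else (
        "solution at bracket edge; data may not be exponential-growth shaped"
        if at_edge
        else str(res.message)
    )

    pred = model_volumes(k1_hat)
    params: dict[str, float] = {"k1": k1_hat}
    if fit_scale:
        if log_objective:
            scale = float(np.exp(np.mean(obs - np.log(np.maximum(pred, 1e-300)))))
        else:
            denom = float(np.dot(pred, pred))
            scale = float(np.dot(pred, data.volumes)) / denom if denom > 0 else 1.0
        params["initial_count_scale"] = scale
        pred = pred * scale
    return _finish_fit(data, pred, params, float(res.fun), converged, message)


def fit_treatment(
    data: TumorDataset,
    k: RateConstants,
    target: str,
    window: tuple[float, float],
    *,
    split_policy: str = "asymptotic",
    log_factor_bounds: tuple[float, float] = (-2.0, 5.0),
    log_objective: bool = False,
    extra_schedule: TreatmentSchedule | None = None,
    targets_together: Sequence[str] | None = None,
    density: float = CELLS_PER_MM3,
) -> FitResult:
    """Fit the multiplier a treatment applies to one rate constant.

    All rate constants are held at the (previously fitted) baseline ``k``;
    the single free parameter is the factor multiplying ``target`` over the
    half-open ``window``.  ``targets_together`` lets the same fitted factor
    act on several rates at once (bulk chemotherapy elevating all three
    death rates).  The search is over log10(factor), bracketed by
    ``log_factor_bounds``; a factor near 1 means no detectable treatment
    effect.
    """
    names = list(targets_together) if targets_together else [target]
    start, end = window
    if not (data.days[0] <= start < end):
        raise ValueError("treatment window must start inside the data range")
    init = initial_state(
        data.initial_total_cells, data.initial_frac_csc, k, split_policy, t0=float(data.days[0])
    )
    obs = np.log(data.volumes) if log_objective else data.volumes

    def make_schedule(factor: float) -> TreatmentSchedule:
        mods = tuple(RateModifier(n, start, end, factor=factor) for n in names)
        if extra_schedule is not None:
            mods = mods + extra_schedule.modifiers
            return TreatmentSchedule(modifiers=mods, events=extra_schedule.events)
        return TreatmentSchedule(modifiers=mods)

    def predict(factor: float) -> np.ndarray:
        return _predict_volumes(k, init, data.days, make_schedule(factor), density)

    def objective(log10_factor: float) -> float:
        pred = predict(10.0 ** log10_factor)
        series = np.log(np.maximum(pred, 1e-300)) if log_objective else pred
        return float(np.sum((obs - series) ** 2))

    res = minimize_scalar(
        objective, bounds=log_factor_bounds, method="bounded", options={"xatol": 1e-9}
    )
    log_hat = float(res.x)
    span = log_factor_bounds[1] - log_factor_bounds[0]
    at_edge = min(log_hat - log_factor_bounds[0], log_factor_bounds[1] - log_hat) < 1e-4 * span
    # flat-objective diagnostic: compare to a 10% perturbed factor
    f_hat = 10.0 ** log_hat
    flat = abs(objective(log_hat + np.log10(1.1)) - res.fun) <= 1e-12 * max(abs(res.fun), 1.0)
    if flat:
        logger.warning(
            "fit_treatment: objective is flat around factor %.4g (target %s); "
            "the multiplier is weakly identified",
            f_hat,
            names,
        )
    converged = bool(res.success) and not at_edge
    message = "" if converged else "solution at factor-bound edge"
    if flat:
        message = (message + "; " if message else "") + "flat objective region"
    pred = predict(f_hat)
    return _finish_fit(
        data, pred, {"factor": f_hat, "targets": names}, float(res.fun), converged, message
    )


def constrained_phi_search(
    data: TumorDataset,
    grid: Mapping[str, Sequence[float]],
    *,
    split_policy: str = "asymptotic",
    log_objective: bool = False,
) -> list[tuple[PhiRatios, FitResult, ConstraintReport]]:
    """Exhaustive grid search over Phi space under the biological constraints.

    ``grid`` maps ratio names (e.g. ``"phi_4_1"``) to candidate values;
    ratios not in the grid stay at the published values.  Constraints are
    scale-invariant (they do not depend on k1), so candidates are screened
    before the 1-D k1 fit.  Returns passing combinations sorted by
    objective; an empty list means no grid point satisfied the constraints.
    """
    from .params import PHI_NAMES, REPORTED_PHI

    unknown = set(grid) - set(PHI_NAMES)
    if unknown:
        raise ValueError(f"unknown phi names in grid: {sorted(unknown)}")
    names = list(grid)
    results: list[tuple[PhiRatios, FitResult, ConstraintReport]] = []
    n_screened = 0
    for values in itertools.product(*(grid[n] for n in names)):
        phi = REPORTED_PHI.replace(**dict(zip(names, values)))
        report = check_constraints(phi_to_rates(phi, 1.0))
        if not report.passed:
            n_screened += 1
            continue
        fit = fit_growth(
            data, phi, split_policy=split_policy, log_objective=log_objective
        )
        results.append((phi, fit, report))
    if not results:
        logger.warning(
            "constrained_phi_search: no grid point passed the constraints "
            "(%d screened out)",
            n_screened,
        )
    results.sort(key=lambda item: item[1].objective)
    return results
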