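"""Run configuration schema and the end-to-end pipeline.

A run is fully reproducible from its config plus seed: the config names
the parameters (absolute rates or ratio form), the initial conditions,
the treatment schedule (inline records or a named scenario), and the
simulation horizon.  ``run_pipeline`` executes the simulation, writes the
trajectory and a JSON report embedding the resolved configuration, and
summarizes relapse and terminal composition.
"""

from __future__ import annotations

import json
import logging
import pathlib
from typing import Any, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .fitting import initial_state
from .model import CELLS_PER_MM3, PopulationState, asymptotic_fractions
from .params import PhiRatios, RateConstants, phi_to_rates
from .scenarios import build_scenario
from .simulate import KillEvent, RateModifier, TreatmentSchedule, relapse_time, simulate

__all__ = ["RunConfig", "load_config", "run_pipeline", "schedule_from_records"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ParameterSpec(BaseModel):
    """Either absolute rates {k1..k8} or ratio form {k1, phi}."""

    k1: float = Field(gt=0)
    k2: Optional[float] = None
    k3: Optional[float] = None
    k4: Optional[float] = None
    k5: Optional[float] = None
    k6: Optional[float] = None
    k7: Optional[float] = None
    k8: Optional[float] = None
    phi: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _exactly_one_form(self) -> "ParameterSpec":
        absolute = [self.k2, self.k3, self.k4, self.k5, self.k6, self.k7, self.k8]
        has_absolute = all(v is not None for v in absolute)
        if self.phi is not None and any(v is not None for v in absolute):
            raise ValueError("give either k2..k8 or phi, not both")
        if self.phi is None and not has_absolute:
            raise ValueError("incomplete absolute form: k2..k8 all required when phi absent")
        return self

    def resolve(self) -> RateConstants:
        if self.phi is not None:
            return phi_to_rates(PhiRatios.from_dict(self.phi), self.k1)
        return RateConstants(
            self.k1, self.k2, self.k3, self.k4, self.k5, self.k6, self.k7, self.k8
        )


class InitialSpec(BaseModel):
    total_cells: float = Field(gt=0)
    frac_csc: float = Field(ge=0, le=1)
    split_policy: Literal["asymptotic", "all_p", "all_d"] = "asymptotic"
    t0: float = 0.0


class ScenarioRef(BaseModel):
    name: str
    start_day: float
    stop_day: float
    kwargs: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated, serializable description of one simulation run."""

    schema_version: int = SCHEMA_VERSION
    parameters: ParameterSpec
    initial: InitialSpec
    t_end: float
    grid_step: float = 0.5
    schedule: list[dict[str, Any]] = Field(default_factory=list)
    scenario: Optional[ScenarioRef] = None
    density: float = CELLS_PER_MM3
    extinction_threshold: float = 1.0
    seed: int = 0
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _checks(self) -> "RunConfig":
        if self.t_end <= self.initial.t0:
            raise ValueError("t_end must exceed initial.t0")
        if self.schedule and self.scenario is not None:
            raise ValueError("give either an inline schedule or a named scenario, not both")
        return self

    def resolve_schedule(self) -> TreatmentSchedule:
        if self.scenario is not None:
            spec = build_scenario(
                self.scenario.name,
                self.scenario.start_day,
                self.scenario.stop_day,
                **self.scenario.kwargs,
            )
            return spec.schedule
        return schedule_from_records(self.schedule)


def schedule_from_records(records: list[dict[str, Any]]) -> TreatmentSchedule:
    """Build a schedule from {type: modifier|kill, ...} records."""
    modifiers: list[RateModifier] = []
    events: list[KillEvent] = []
    for i, rec in enumerate(records):
        kind = rec.get("type")
        try:
            if kind == "modifier":
                modifiers.append(
                    RateModifier(
                        target=rec["target"],
                        start=float(rec["start"]),
                        end=float(rec["end"]),
                        factor=rec.get("factor"),
                        replace=rec.get("replace"),
                    )
                )
            elif kind == "kill":
                f = rec["fractions"]
                events.append(KillEvent(t=float(rec["t"]), f_csc=f[0], f_p=f[1], f_d=f[2]))
            else:
                raise ValueError(f"type must be 'modifier' or 'kill', got {kind!r}")
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"schedule record {i}: {exc}") from exc
    return TreatmentSchedule(modifiers=tuple(modifiers), events=tuple(events))


def load_config(path: str | pathlib.Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    path = pathlib.Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(raw)


def run_pipeline(config: RunConfig, out_dir: str | pathlib.Path | None = None) -> dict:
    """Simulate per config, write outputs, and return the run report."""
    k = config.parameters.resolve()
    init = initial_state(
        config.initial.total_cells,
        config.initial.frac_csc,
        k,
        config.initial.split_policy,
        t0=config.initial.t0,
    )
    schedule = config.resolve_schedule()
    logger.info("resolved rate constants: %s", k.to_dict())
    logger.info(
        "schedule: %d modifiers, %d events, breakpoints %s",
        len(schedule.modifiers),
        len(schedule.events),
        schedule.breakpoints(config.initial.t0, config.t_end),
    )
    traj = simulate(
        k,
        init,
        schedule,
        t_end=config.t_end,
        grid_step=config.grid_step,
        extinction_threshold=config.extinction_threshold,
        density=config.density,
    )
    treated = not schedule.empty
    relapse = relapse_time(traj) if treated else None
    mode = asymptotic_fractions(k)
    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.model_dump(mode="json"),
        "resolved_rates": k.to_dict(),
        "initial_state": {"t": init.t, "csc": init.csc, "p": init.p, "d": init.d},
        "schedule_breakpoints": list(traj.treatment_breakpoints),
        "final": {
            "day": float(traj.times[-1]),
            "n": float(traj.n[-1]),
            "volume_mm3": float(traj.volume[-1]),
            "frac_csc": float(traj.frac_csc[-1]),
            "frac_p": float(traj.frac_p[-1]),
        },
        "asymptotic_mode": {
            "f_csc": mode.f_csc,
            "f_p": mode.f_p,
            "f_d": mode.f_d,
            "dominant": mode.dominant,
        },
        "relapse_day": relapse,
        "relapse_detected": relapse is not None,
    }
    target = out_dir or config.out_dir
    if target is not None:
        target = pathlib.Path(target)
        target.mkdir(parents=True, exist_ok=True)
        traj.to_csv(target / "trajectory.csv")
        (target / "report.json").write_text(json.dumps(report, indent=2))
    return report
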