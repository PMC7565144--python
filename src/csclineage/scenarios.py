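"""Named treatment scenarios for the hierarchy model.

Each builder returns a ready-made :class:`~csclineage.simulate.TreatmentSchedule`
for one of the therapy configurations studied with this model: nonselective
bulk kills, selective CSC or progenitor killing, forced differentiation,
their combinations, and the ovarian-cancer chemotherapy/CPI613 presets.

Multipliers that are fixed by the model study are hard-wired (k6 x 100,
k7 x 15, k5 x 1.375 for the Phi_5/4 0.8 -> 1.1 boost, k5 x 1.2, k1 / 1000,
k7 x 100, k6 x 200).  The chemotherapy and CPI613 death-rate elevations were
never published as numbers; they are exposed as free keyword arguments with
documented defaults and are meant to be calibrated with
:func:`csclineage.fitting.fit_treatment`.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

from .simulate import KillEvent, RateModifier, TreatmentSchedule

__all__ = ["ScenarioSpec", "build_scenario", "list_scenarios", "BULK_KILL_FRACTIONS"]

#: Bulk kill fractions of the nonselective-treatment comparison.
BULK_KILL_FRACTIONS = (0.95, 0.99, 0.999, 0.9999)

#: Relative k5 increase equivalent to raising Phi_5/4 from 0.8 to 1.1.
DIFFERENTIATION_BOOST_FACTOR = 1.1 / 0.8  # = 1.375


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A named, documented treatment schedule."""

    name: str
    schedule: TreatmentSchedule
    description: str


def _window(start: float, stop: float) -> tuple[float, float]:
    if not start < stop:
        raise ValueError(f"scenario requires start_day < stop_day, got {start} >= {stop}")
    return start, stop


def _nonselective_kill(f: float):
    def build(start: float, stop: float, **_: float) -> TreatmentSchedule:
        return TreatmentSchedule(events=(KillEvent(t=start, f_csc=f, f_p=f, f_d=f),))

    return build, f"instantaneous nonselective elimination of {f:.2%} of all compartments"


def _csc_kill_100x(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(modifiers=(RateModifier("k6", s, e, factor=100.0),))


def _bulk99_except_csc(start: float, stop: float, **_: float) -> TreatmentSchedule:
    return TreatmentSchedule(events=(KillEvent(t=start, f_csc=0.0, f_p=0.99, f_d=0.99),))


def _p_kill_15x(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(modifiers=(RateModifier("k7", s, e, factor=15.0),))


def _differentiation_boost(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(RateModifier("k5", s, e, factor=DIFFERENTIATION_BOOST_FACTOR),)
    )


def _combo_a(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(
            RateModifier("k6", s, e, factor=100.0),
            RateModifier("k7", s, e, factor=15.0),
        )
    )


def _combo_b(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(
            RateModifier("k5", s, e, factor=1.20),
            RateModifier("k6", s, e, factor=100.0),
        )
    )


def _combo_c(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(
            RateModifier("k1", s, e, factor=0.001),
            RateModifier("k7", s, e, factor=100.0),
        )
    )


def _combo_c_plus(start: float, stop: float, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(
            RateModifier("k1", s, e, factor=0.001),
            RateModifier("k7", s, e, factor=100.0),
            RateModifier("k6", s, e, factor=200.0),
        )
    )


def _chemo(start: float, stop: float, *, death_factor: float = 10.0, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(
        modifiers=(
            RateModifier("k6", s, e, factor=death_factor),
            RateModifier("k7", s, e, factor=death_factor),
            RateModifier("k8", s, e, factor=death_factor),
        )
    )


def _cpi613(start: float, stop: float, *, death_factor: float = 100.0, **_: float) -> TreatmentSchedule:
    s, e = _window(start, stop)
    return TreatmentSchedule(modifiers=(RateModifier("k6", s, e, factor=death_factor),))


_LIBRARY: dict[str, tuple[Callable[..., TreatmentSchedule], str]] = {
    "csc_kill_100x": (
        _csc_kill_100x,
        "selective CSC killing: 100-fold elevation of the CSC death rate k6 over the window",
    ),
    "bulk99_except_csc": (
        _bulk99_except_csc,
        "instantaneous 99% kill of P and D compartments, sparing CSCs",
    ),
    "p_kill_15x": (
        _p_kill_15x,
        "selective progenitor killing: 15-fold elevation of k7 over the window",
    ),
    "differentiation_boost": (
        _differentiation_boost,
        "forced progenitor differentiation: Phi_5/4 raised 0.8 -> 1.1 (k5 x 1.375)",
    ),
    "combo_A": (_combo_a, "combined CSC (k6 x 100) and P (k7 x 15) killing"),
    "combo_B": (_combo_b, "k5 raised 20% plus CSC killing (k6 x 100)"),
    "combo_C": (_combo_c, "CSC renewal inhibition (k1 / 1000) plus P killing (k7 x 100)"),
    "combo_C_plus": (
        _combo_c_plus,
        "combo_C plus 200-fold CSC death-rate elevation (k6 x 200)",
    ),
    "chemo": (
        _chemo,
        "bulk cytotoxic chemotherapy: equal death-rate elevation of all three "
        "compartments over the window (death_factor keyword; calibrate by fitting)",
    ),
    "cpi613": (
        _cpi613,
        "CSC-selective metabolic inhibitor: k6 elevation over the window "
        "(death_factor keyword; calibrate by fitting)",
    ),
}
for _f in BULK_KILL_FRACTIONS:
    _LIBRARY[f"nonselective_kill_{_f}"] = _nonselective_kill(_f)


def list_scenarios() -> list[str]:
    """Names of every available scenario."""
    return sorted(_LIBRARY)


def build_scenario(
    name: str, start_day: float, stop_day: float, **kwargs: float
) -> ScenarioSpec:
    """Build a named scenario over the half-open window [start_day, stop_day).

    Kill-event scenarios place their event at ``start_day``; windowed
    scenarios modify rates over the full window.  Unknown names raise a
    ValueError listing the valid ones.
    """
    if name not in _LIBRARY:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(list_scenarios())}"
        )
    builder, description = _LIBRARY[name]
    schedule = builder(start_day, stop_day, **kwargs)
    return ScenarioSpec(name=name, schedule=schedule, description=description)
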