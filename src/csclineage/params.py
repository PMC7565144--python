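"""Kinetic parameterization of the three-compartment stem-cell hierarchy.

The tumor is modelled as a unidirectional cell lineage: cancer stem cells
(CSC) sit at the apex, produce intermediate progenitor (P) cells, which in
turn produce terminally differentiated (D) cells.  Every cellular event is
a first-order pseudo-reaction with one rate constant (per day):

======  =====================================  ==========================
rate    event                                  reaction
======  =====================================  ==========================
``k1``  CSC symmetric self-renewal             CSC -> 2 CSC
``k2``  CSC asymmetric division                CSC -> CSC + P
``k3``  CSC symmetric differentiation          CSC -> 2 P
``k4``  P symmetric self-renewal               P -> 2 P
``k5``  P terminal differentiation             P -> 2 D
``k6``  CSC death                              CSC -> (removed)
``k7``  P death                                P -> (removed)
``k8``  D death                                D -> (removed)
======  =====================================  ==========================

Because only the ratios of rate constants determine the shape of the
dynamics (a common rescaling only changes the time unit), the parameter
space is usually expressed as dimensionless ratios ``Phi_i/j = k_i / k_j``
relative to ``k1`` -- with the single exception of ``Phi_5/4 = k5 / k4``,
which is defined against the progenitor renewal rate.  The published
solution of this model is::

    Phi_2/1 = 1, Phi_3/1 = 0.01, Phi_4/1 = 5.35, Phi_5/4 = 0.8,
    Phi_6/1 = 0.01, Phi_7/1 = 0.1, Phi_8/1 = 1

which, at ``k1 = 1``, gives ``k = (1, 1, 0.01, 5.35, 4.28, 0.01, 0.1, 1)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "RATE_NAMES",
    "PHI_NAMES",
    "RateConstants",
    "PhiRatios",
    "REPORTED_PHI",
    "phi_to_rates",
    "rates_to_phi",
    "reported_rates",
    "load_parameters",
]

RATE_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")
PHI_NAMES = (
    "phi_2_1",
    "phi_3_1",
    "phi_4_1",
    "phi_5_4",
    "phi_6_1",
    "phi_7_1",
    "phi_8_1",
)


def _check_nonnegative_finite(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclasses.dataclass(frozen=True)
class RateConstants:
    """The eight first-order rate constants of the hierarchy, per day."""

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = float(getattr(self, name))
            _check_nonnegative_finite(name, value)
            object.__setattr__(self, name, value)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in RATE_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateConstants":
        missing = [n for n in RATE_NAMES if n not in d]
        if missing:
            raise ValueError(f"missing rate constants: {missing}")
        extra = [n for n in d if n not in RATE_NAMES]
        if extra:
            raise ValueError(f"unknown rate constants: {extra}")
        return cls(**{n: float(d[n]) for n in RATE_NAMES})

    def replace(self, **changes: float) -> "RateConstants":
        return dataclasses.replace(self, **changes)

    def scaled(self, factor: float) -> "RateConstants":
        """Rescale every rate by a common factor (changes only the time unit)."""
        if factor < 0:
            raise ValueError("scaling factor must be >= 0")
        return RateConstants(*(factor * v for v in self.as_array()))


@dataclasses.dataclass(frozen=True)
class PhiRatios:
    """Dimensionless rate ratios defining the parameter space relative to k1.

    ``phi_5_4`` is the odd one out: it relates the progenitor terminal
    differentiation rate k5 to the progenitor renewal rate k4, not to k1.
    """

    phi_2_1: float
    phi_3_1: float
    phi_4_1: float
    phi_5_4: float
    phi_6_1: float
    phi_7_1: float
    phi_8_1: float

    def __post_init__(self) -> None:
        for name in PHI_NAMES:
            value = float(getattr(self, name))
            _check_nonnegative_finite(name, value)
            object.__setattr__(self, name, value)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PHI_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PHI_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PhiRatios":
        missing = [n for n in PHI_NAMES if n not in d]
        if missing:
            raise ValueError(f"missing phi ratios: {missing}")
        extra = [n for n in d if n not in PHI_NAMES]
        if extra:
            raise ValueError(f"unknown phi ratios: {extra}")
        return cls(**{n: float(d[n]) for n in PHI_NAMES})

    def replace(self, **changes: float) -> "PhiRatios":
        return dataclasses.replace(self, **changes)


#: The published solution of the constrained parameter search.
REPORTED_PHI = PhiRatios(
    phi_2_1=1.0,
    phi_3_1=0.01,
    phi_4_1=5.35,
    phi_5_4=0.8,
    phi_6_1=0.01,
    phi_7_1=0.1,
    phi_8_1=1.0,
)


def phi_to_rates(phi: PhiRatios, k1: float) -> RateConstants:
    """Convert ratio-space parameters to absolute rate constants.

    All ratios scale k1 directly except ``phi_5_4``, which scales k4, so
    ``k5 = k1 * phi_4_1 * phi_5_4``.
    """
    if not math.isfinite(k1) or k1 < 0:
        raise ValueError(f"k1 must be finite and >= 0, got {k1!r}")
    k4 = k1 * phi.phi_4_1
    return RateConstants(
        k1=k1,
        k2=k1 * phi.phi_2_1,
        k3=k1 * phi.phi_3_1,
        k4=k4,
        k5=k4 * phi.phi_5_4,
        k6=k1 * phi.phi_6_1,
        k7=k1 * phi.phi_7_1,
        k8=k1 * phi.phi_8_1,
    )


def rates_to_phi(k: RateConstants) -> PhiRatios:
    """Exact inverse of :func:`phi_to_rates`; requires k1 > 0 and k4 > 0."""
    if k.k1 == 0:
        raise ValueError("phi ratios are undefined when k1 == 0")
    if k.k4 == 0:
        raise ValueError("phi_5_4 is undefined when k4 == 0")
    return PhiRatios(
        phi_2_1=k.k2 / k.k1,
        phi_3_1=k.k3 / k.k1,
        phi_4_1=k.k4 / k.k1,
        phi_5_4=k.k5 / k.k4,
        phi_6_1=k.k6 / k.k1,
        phi_7_1=k.k7 / k.k1,
        phi_8_1=k.k8 / k.k1,
    )


def reported_rates(k1: float = 1.0) -> RateConstants:
    """Absolute rate constants of the published parameter set at the given k1."""
    return phi_to_rates(REPORTED_PHI, k1)


def load_parameters(path: str | pathlib.Path) -> RateConstants:
    """Load rate constants from a flat JSON/YAML file.

    Exactly one of two layouts is accepted:

    * absolute form: ``{k1: ..., ..., k8: ...}``
    * ratio form: ``{k1: ..., phi: {phi_2_1: ..., ...}}``
    """
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    if "phi" in raw:
        extra = set(raw) - {"k1", "phi"}
        if extra:
            raise ValueError(
                f"{path}: ratio-form file allows only 'k1' and 'phi', got {sorted(extra)}"
            )
        if "k1" not in raw:
            raise ValueError(f"{path}: ratio-form file requires 'k1'")
        phi = PhiRatios.from_dict(raw["phi"])
        return phi_to_rates(phi, float(raw["k1"]))
    return RateConstants.from_dict(raw)
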