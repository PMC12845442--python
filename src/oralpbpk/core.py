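"""Domain types, unit canonicalization and parameter validation.

The internal (canonical) unit system is

    length  cm
    time    min
    amount  µg
    volume  mL

Physiology parameters are typically quoted in mixed units (salivary flow in
mL/min, pocket volume and crevicular-fluid flow in µL, biofilm diffusivity in
cm²/s).  :func:`to_canonical` converts a parameter set into the canonical
system exactly once; parameter objects carry a unit tag so that an accidental
double conversion is detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterator

__all__ = [
    "OralPhysiology",
    "DoseEvent",
    "DoseRoute",
    "RangeWarning",
    "USER_UNITS",
    "CANONICAL_UNITS",
    "TYPICAL_RANGES",
    "validate_physiology",
    "to_canonical",
    "from_canonical",
]


class DoseRoute(str, Enum):
    """How a dose enters the system."""

    SALIVA_BOLUS = "saliva_bolus"
    SALIVA_INFUSION = "saliva_infusion"
    POCKET_FORMULATION = "pocket_formulation"


#: unit of each OralPhysiology field as the user supplies it
USER_UNITS: dict[str, str] = {
    "V_S": "mL",
    "Q_S": "mL/min",
    "R_in": "ug/min",
    "A_SM": "cm^2",
    "A_SB": "cm^2",
    "A_SP": "cm^2",
    "Gamma_max": "ug/cm^2",
    "k_ads": "mL/cm^2/min",
    "k_des": "1/min",
    "P_SM": "cm/min",
    "K_p_T": "1",
    "V_T": "mL",
    "CL_local": "mL/min",
    "D_eff": "cm^2/s",
    "k_bind": "1/s",
    "L_B": "cm",
    "A_BP": "cm^2",
    "V_P": "uL",
    "Q_GCF": "uL/min",
}

#: unit of each field in the canonical (cm, min, µg, mL) system
CANONICAL_UNITS: dict[str, str] = dict(
    USER_UNITS,
    D_eff="cm^2/min",
    k_bind="1/min",
    V_P="mL",
    Q_GCF="mL/min",
)

# multiplicative factor user -> canonical for the fields that change
_CONVERSIONS: dict[str, float] = {
    "D_eff": 60.0,  # cm²/s -> cm²/min
    "k_bind": 60.0,  # 1/s -> 1/min
    "V_P": 1e-3,  # µL -> mL
    "Q_GCF": 1e-3,  # µL/min -> mL
}

#: typical ranges printed for the five-region system, in user units.
#: Q_S spans resting (0.3–0.5) through stimulated (1–2) flow; Q_GCF spans
#: healthy (0.05–0.1) through inflamed (0.2–0.5) pockets.
TYPICAL_RANGES: dict[str, tuple[float, float]] = {
    "V_S": (0.7, 1.0),
    "Q_S": (0.3, 2.0),
    "Gamma_max": (5.0, 15.0),
    "k_ads": (0.1, 1.2),
    "k_des": (0.01, 0.1),
    "P_SM": (1e-5, 1e-4),
    "K_p_T": (2.0, 10.0),
    "V_T": (0.05, 0.1),
    "A_SM": (2.0, 6.0),
    "CL_local": (0.01, 0.1),
    "D_eff": (1e-7, 5e-7),
    "L_B": (0.01, 0.03),
    "V_P": (0.5, 2.0),
    "Q_GCF": (0.05, 0.5),
}

# fields that must be strictly positive even in degenerate scenarios
_STRICTLY_POSITIVE = (
    "V_S",
    "K_p_T",
    "V_T",
    "D_eff",
    "L_B",
    "V_P",
)
# rates/flows that may legitimately be zero (closed-system limits); Q_S is
# here so degenerate closed systems can be constructed, but validate_physiology
# still treats a non-positive salivary flow as an error
_NON_NEGATIVE = (
    "Q_S",
    "A_SM",
    "A_SB",
    "A_SP",
    "A_BP",
    "R_in",
    "Gamma_max",
    "k_ads",
    "k_des",
    "P_SM",
    "CL_local",
    "k_bind",
    "Q_GCF",
)


@dataclass(frozen=True)
class OralPhysiology:
    """Anatomical, flow and transport parameters of the five-region system.

    Saliva (S), pellicle-covered mucosal surface (M), mucosal tissue (T),
    dental biofilm (B) and periodontal pocket (P).  Field units are those of
    ``USER_UNITS`` unless ``unit_system == "canonical"``.
    """

    V_S: float  # saliva volume [mL]
    Q_S: float  # salivary flow [mL/min]
    A_SM: float  # saliva–mucosa interface area [cm²]
    A_SB: float  # saliva–biofilm interface area [cm²]
    A_SP: float  # saliva–pocket interface area [cm²]
    Gamma_max: float  # pellicle binding capacity [µg/cm²]
    k_ads: float  # adsorption rate [mL·cm⁻²·min⁻¹]
    k_des: float  # desorption rate [1/min]
    P_SM: float  # transmucosal permeability [cm/min]
    K_p_T: float  # tissue:saliva partition coefficient [–]
    V_T: float  # mucosal tissue volume [mL]
    CL_local: float  # local tissue clearance [mL/min]
    D_eff: float  # effective biofilm diffusivity [cm²/s user, cm²/min canonical]
    k_bind: float  # biofilm binding rate [1/s user, 1/min canonical]
    L_B: float  # biofilm thickness [cm]
    A_BP: float  # biofilm–pocket interface area [cm²]
    V_P: float  # pocket volume [µL user, mL canonical]
    Q_GCF: float  # gingival crevicular fluid flow [µL/min user, mL/min canonical]
    R_in: float = 0.0  # constant drug input rate into saliva [µg/min]
    unit_system: str = "user"

    def __post_init__(self) -> None:
        if self.unit_system not in ("user", "canonical"):
            raise ValueError(f"unknown unit system {self.unit_system!r}")
        for name in _STRICTLY_POSITIVE:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    def replace(self, **changes: float) -> "OralPhysiology":
        return replace(self, **changes)

    def items(self) -> Iterator[tuple[str, float]]:
        for f in fields(self):
            if f.name != "unit_system":
                yield f.name, getattr(self, f.name)


@dataclass(frozen=True)
class RangeWarning:
    """A parameter outside its typical physiological range (not an error)."""

    parameter: str
    value: float
    low: float
    high: float
    unit: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.parameter} = {self.value:g} {self.unit} outside typical "
            f"range {self.low:g}–{self.high:g} {self.unit}"
        )


def validate_physiology(p: OralPhysiology) -> list[RangeWarning]:
    """Check a parameter set against the typical physiological ranges.

    Returns one :class:`RangeWarning` per parameter lying outside its printed
    range.  The ranges are illustrative, so out-of-range values warn rather
    than raise; non-positive volumes, flows, areas or transport coefficients
    raise ``ValueError``.
    """
    for name in ("Q_S", "Q_GCF", "k_ads", "k_des", "P_SM", "CL_local",
                 "Gamma_max", "k_bind", "A_SM", "A_SB", "A_SP", "A_BP"):
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be strictly positive, got {getattr(p, name)!r}")
    units = USER_UNITS if p.unit_system == "user" else CANONICAL_UNITS
    warnings: list[RangeWarning] = []
    for name, (lo, hi) in TYPICAL_RANGES.items():
        value = getattr(p, name)
        if p.unit_system == "canonical" and name in _CONVERSIONS:
            lo, hi = lo * _CONVERSIONS[name], hi * _CONVERSIONS[name]
        if not (lo <= value <= hi):
            warnings.append(RangeWarning(name, value, lo, hi, units[name]))
    return warnings


def to_canonical(p: OralPhysiology) -> OralPhysiology:
    """Convert a parameter set to the canonical (cm, min, µg, mL) system.

    Idempotent: a set already tagged canonical is returned unchanged.
    """
    if p.unit_system == "canonical":
        return p
    changes = {name: getattr(p, name) * f for name, f in _CONVERSIONS.items()}
    return replace(p, unit_system="canonical", **changes)


def from_canonical(p: OralPhysiology) -> OralPhysiology:
    """Inverse of :func:`to_canonical`; identity on user-tagged sets."""
    if p.unit_system == "user":
        return p
    changes = {name: getattr(p, name) / f for name, f in _CONVERSIONS.items()}
    return replace(p, unit_system="user", **changes)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration.

    ``saliva_bolus``: instantaneous increment of the salivary concentration by
    ``amount / V_S`` at ``start``.  ``saliva_infusion``: constant input
    ``amount / duration`` into saliva over ``[start, start + duration]``.
    ``pocket_formulation``: a subgingivally placed carrier whose release-rate
    function drives the pocket source term, with ``amount`` as the total
    releasable dose.
    """

    amount: float  # µg
    route: DoseRoute = DoseRoute.SALIVA_BOLUS
    start: float = 0.0  # min
    duration: float = 0.0  # min (infusion / formulation only)

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", DoseRoute(self.route))
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount!r}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration!r}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start!r}")
        if self.route is DoseRoute.SALIVA_INFUSION and self.duration == 0:
            raise ValueError("saliva_infusion requires a positive duration")
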