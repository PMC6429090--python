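"""Light-dose and geometry bookkeeping for the CAM PDT experiment.

Fluence (light dose, J/cm^2) is irradiance (mW/cm^2) times exposure time
(s) divided by 1000.  The treatment field is bounded by a Teflon ring of
1.5 cm diameter (area pi * 0.75^2 ~= 1.767 cm^2, displayed as "1.76" under
the two-decimal truncation rule used in reports).

The built-in group table encodes the 20 experimental conditions: five
light-only groups (L1-L5), six curcumin-only groups (C1-C6, areal
concentrations 0.1-10 mM/cm^2), and nine PDT groups (PDT1-PDT9).  The
"mM/cm^2" areal-concentration unit is kept as an opaque condition label
(solution molarity applied over the ring area).  Exposure durations not
printed per-row are reconstructed from fluence / irradiance consistency
(600 s everywhere except the 15 J/cm^2 rows at 300 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def fluence(irradiance_mw_cm2: float, duration_s: float) -> float:
    """Light dose in J/cm^2 from irradiance (mW/cm^2) and exposure (s)."""
    if irradiance_mw_cm2 < 0:
        raise ValueError(f"irradiance must be >= 0, got {irradiance_mw_cm2}")
    if duration_s < 0:
        raise ValueError(f"duration must be >= 0, got {duration_s}")
    return irradiance_mw_cm2 * duration_s / 1000.0


def ring_area(diameter_cm: float = 1.5) -> float:
    """Ring field area pi * (d/2)^2 in cm^2, full precision."""
    if diameter_cm <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_cm}")
    return math.pi * (diameter_cm / 2.0) ** 2


def truncate_2dp(value: float) -> str:
    """Two-decimal truncation display rule (1.7671... -> \"1.76\")."""
    return f"{math.floor(value * 100) / 100:.2f}"


@dataclass
class ExposureSettings:
    irradiance_mw_cm2: float
    duration_s: float

    @property
    def fluence_j_cm2(self) -> float:
        return fluence(self.irradiance_mw_cm2, self.duration_s)


@dataclass
class RingGeometry:
    diameter_cm: float = 1.5

    @property
    def area_cm2(self) -> float:
        return ring_area(self.diameter_cm)


@dataclass
class GroupDefinition:
    """One experimental condition: light only, curcumin only, or PDT."""

    name: str
    curcumin_mM_cm2: float | None  # areal-concentration label; None = no PS
    exposure: ExposureSettings | None  # None = no irradiation

    @property
    def fluence_j_cm2(self) -> float | None:
        return None if self.exposure is None else self.exposure.fluence_j_cm2


_CONCENTRATIONS = (0.1, 0.33, 0.5, 1.0, 5.0, 10.0)


def load_group_table() -> list[GroupDefinition]:
    """The 20 experimental conditions (5 light-only, 6 curcumin-only, 9 PDT)."""
    groups: list[GroupDefinition] = [
        GroupDefinition("L1", None, ExposureSettings(10, 600)),   # 6 J/cm^2
        GroupDefinition("L2", None, ExposureSettings(12, 600)),   # 7.2 J/cm^2
        GroupDefinition("L3", None, ExposureSettings(50, 300)),   # 15 J/cm^2
        GroupDefinition("L4", None, ExposureSettings(50, 600)),   # 30 J/cm^2
        GroupDefinition("L5", None, ExposureSettings(60, 600)),   # 36 J/cm^2
    ]
    for i, conc in enumerate(_CONCENTRATIONS, start=1):
        groups.append(GroupDefinition(f"C{i}", conc, None))
    for i, conc in enumerate(_CONCENTRATIONS, start=1):
        groups.append(GroupDefinition(f"PDT{i}", conc, ExposureSettings(50, 600)))
    for i, conc in enumerate((0.1, 0.5, 1.0), start=7):
        groups.append(GroupDefinition(f"PDT{i}", conc, ExposureSettings(50, 300)))
    return groups


def get_group(name: str) -> GroupDefinition:
    for g in load_group_table():
        if g.name == name:
            return g
    raise KeyError(f"unknown group {name!r}")
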