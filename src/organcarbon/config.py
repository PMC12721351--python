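"""Shared configuration: policy calendar, emission factors, scenario thresholds.

Acuity-circle (AC) allocation replaced donor-service-area-based organ
allocation with fixed-radius priority circles around the donor hospital,
on a different date for each solid organ. The policy calendar below holds
those implementation dates and the end of the observation data; emission
factors hold the per-mile carbon intensities used to convert organ travel
into kg CO2e.

Everything here is an input, not a constant of nature: real analyses can
override the calendar, the threshold grid and the factor file.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import yaml

ORGANS = ("heart", "lung", "liver", "kidney")

#: Organs assumed to fly by dedicated charter aircraft when they fly.
CHARTER_ORGANS = frozenset({"heart", "lung", "liver"})

#: Mean Earth radius in statute miles (spherical model).
DEFAULT_EARTH_RADIUS_MILES = 3958.8

#: Distance thresholds (miles) of the travel-mode scenario grid.
DEFAULT_THRESHOLDS = (25.0, 50.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class PolicyCalendar:
    """Per-organ AC implementation dates and the end of study data."""

    implementation_dates: dict[str, dt.date] = field(
        default_factory=lambda: {
            "lung": dt.date(2017, 11, 24),
            "heart": dt.date(2018, 10, 18),
            "liver": dt.date(2020, 2, 4),
            "kidney": dt.date(2021, 3, 15),
        }
    )
    study_end: dt.date = dt.date(2023, 11, 30)

    def __post_init__(self) -> None:
        for organ, impl in self.implementation_dates.items():
            if impl >= self.study_end:
                raise ValueError(
                    f"{organ}: implementation {impl} not before study end {self.study_end}"
                )

    def implementation_date(self, organ: str) -> dt.date:
        try:
            return self.implementation_dates[organ]
        except KeyError:
            raise KeyError(f"unknown organ {organ!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "PolicyCalendar":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dates = {k: _as_date(v) for k, v in raw["implementation_dates"].items()}
        return cls(implementation_dates=dates, study_end=_as_date(raw["study_end"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "implementation_dates": {
                        k: v.isoformat() for k, v in self.implementation_dates.items()
                    },
                    "study_end": self.study_end.isoformat(),
                },
                fh,
            )


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class EmissionFactors:
    """Per-mile carbon intensities (kg CO2e / mile) by travel mode.

    drive
        Ground transport by a large petrol car (UK DESNZ conversion-factor
        category "large car", petrol; ~0.278 kg CO2e/km).
    charter
        Dedicated short-haul charter aircraft, whole-aircraft attribution,
        assuming two travellers (~200 kg added payload) per procurement.
        The default 2.06 kg CO2e/mi is a light-jet figure on that basis.
    commercial
        Organ carried on a scheduled flight that would fly anyway; no
        added emissions are attributed, hence exactly 0 by default.
    """

    drive_kg_per_mile: float = 0.448
    charter_kg_per_mile: float = 2.06
    commercial_kg_per_mile: float = 0.0
    source: str = "UK DESNZ greenhouse-gas conversion factors"
    vintage: str = "2023"

    def __post_init__(self) -> None:
        for name in ("drive_kg_per_mile", "charter_kg_per_mile", "commercial_kg_per_mile"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def factor(self, mode: str) -> float:
        try:
            return {
                "drive": self.drive_kg_per_mile,
                "charter": self.charter_kg_per_mile,
                "commercial": self.commercial_kg_per_mile,
            }[mode]
        except KeyError:
            raise KeyError(f"unknown travel mode {mode!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "EmissionFactors":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: raw[k] for k in raw if k in cls.__dataclass_fields__})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "drive_kg_per_mile": self.drive_kg_per_mile,
                    "charter_kg_per_mile": self.charter_kg_per_mile,
                    "commercial_kg_per_mile": self.commercial_kg_per_mile,
                    "source": self.source,
                    "vintage": self.vintage,
                },
                fh,
            )
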