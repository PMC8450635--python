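"""Phanerozoic timescale: periods, eras, and age binning.

The analysis bins everything at period level, with the Carboniferous kept
as a single (undivided) period so that period-level binning matches the
convention of Paleobiology Database exports.  Period boundaries follow the
ICS 2020 chart.  Era durations used for per-Myr rates are pinned to the
rounded values conventionally quoted for the Phanerozoic eras (Paleozoic
289, Mesozoic 185, Cenozoic 66 Myr) so that worked-example rates come out
at the familiar printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache


class OutOfRangeError(ValueError):
    """Age falls outside the Phanerozoic (0–541 Ma)."""


@dataclass(frozen=True)
class GeoInterval:
    """A named geologic interval with age bounds in Ma (older bound first)."""

    name: str
    level: str  # "period" or "era"
    max_ma: float
    min_ma: float
    era: str | None = None  # parent era; set for periods only

    def __post_init__(self) -> None:
        if not self.max_ma > self.min_ma >= 0:
            raise ValueError(
                f"invalid bounds for {self.name}: ({self.max_ma}, {self.min_ma})"
            )

    @property
    def midpoint_ma(self) -> float:
        return (self.max_ma + self.min_ma) / 2.0

    @property
    def duration_myr(self) -> float:
        return self.max_ma - self.min_ma

    def contains(self, age_ma: float) -> bool:
        """Closed-interval membership test (both bounds inclusive)."""
        return self.min_ma <= age_ma <= self.max_ma


# (name, max_ma, min_ma, era), ordered old -> young; ICS 2020 boundaries.
_PERIOD_ROWS: tuple[tuple[str, float, float, str], ...] = (
    ("Cambrian", 541.0, 485.4, "Paleozoic"),
    ("Ordovician", 485.4, 443.8, "Paleozoic"),
    ("Silurian", 443.8, 419.2, "Paleozoic"),
    ("Devonian", 419.2, 358.9, "Paleozoic"),
    ("Carboniferous", 358.9, 298.9, "Paleozoic"),
    ("Permian", 298.9, 251.902, "Paleozoic"),
    ("Triassic", 251.902, 201.3, "Mesozoic"),
    ("Jurassic", 201.3, 145.0, "Mesozoic"),
    ("Cretaceous", 145.0, 66.0, "Mesozoic"),
    ("Paleogene", 66.0, 23.03, "Cenozoic"),
    ("Neogene", 23.03, 2.58, "Cenozoic"),
    ("Quaternary", 2.58, 0.0, "Cenozoic"),
)

_ERA_ROWS: tuple[tuple[str, float, float], ...] = (
    ("Paleozoic", 541.0, 251.902),
    ("Mesozoic", 251.902, 66.0),
    ("Cenozoic", 66.0, 0.0),
)

#: Era durations (Myr) used as denominators for per-Myr rates.  Pinned to the
#: rounded, conventionally quoted values rather than the exact boundary
#: differences (289.098, 185.902, 66.0).
ERA_DURATION_MYR: dict[str, float] = {
    "Paleozoic": 289.0,
    "Mesozoic": 185.0,
    "Cenozoic": 66.0,
}

PHANEROZOIC_MAX_MA = 541.0


class Timescale:
    """The Phanerozoic period/era table with age-assignment helpers."""

    def __init__(self) -> None:
        self.periods: tuple[GeoInterval, ...] = tuple(
            GeoInterval(name, "period", mx, mn, era)
            for name, mx, mn, era in _PERIOD_ROWS
        )
        self.eras: tuple[GeoInterval, ...] = tuple(
            GeoInterval(name, "era", mx, mn) for name, mx, mn in _ERA_ROWS
        )
        self._period_by_name = {p.name: p for p in self.periods}
        self._era_by_name = {e.name: e for e in self.eras}

    @property
    def intervals(self) -> tuple[GeoInterval, ...]:
        return self.periods + self.eras

    def period(self, name: str) -> GeoInterval:
        return self._period_by_name[name]

    def era(self, name: str) -> GeoInterval:
        return self._era_by_name[name]

    def period_index(self, name: str) -> int:
        """Index of a period in old -> young order."""
        return [p.name for p in self.periods].index(name)

    def era_duration_myr(self, era_name: str) -> float:
        return ERA_DURATION_MYR[era_name]

    def assign(self, age_ma: float) -> tuple[GeoInterval, GeoInterval]:
        """Period and era containing an age.

        Boundary ages resolve to the younger interval (an age of exactly
        66.0 Ma is Paleogene, not Cretaceous); the oldest bound 541.0 Ma
        belongs to the Cambrian as there is no older Phanerozoic period.
        """
        if not (0.0 <= age_ma <= PHANEROZOIC_MAX_MA):
            raise OutOfRangeError(
                f"age {age_ma} Ma is outside the Phanerozoic [0, 541] Ma"
            )
        for p in self.periods:
            # (min, max] membership puts a shared boundary age in the
            # younger of the two periods meeting there
            if p.min_ma < age_ma <= p.max_ma or (age_ma == 0.0 and p.min_ma == 0.0):
                return p, self._era_by_name[p.era]
        raise OutOfRangeError(f"age {age_ma} Ma not covered by any period")


@lru_cache(maxsize=1)
def load_timescale() -> Timescale:
    """The 12 Phanerozoic periods (Carboniferous undivided) and 3 eras."""
    return Timescale()


def assign_interval(age_ma: float) -> tuple[GeoInterval, GeoInterval]:
    """Module-level convenience wrapper around :meth:`Timescale.assign`."""
    return load_timescale().assign(age_ma)
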