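"""Geographic hierarchy and reporting calendar.

Districts nest in provinces, provinces in countries.  Food-insecurity
phases are reported at period-end months: four times per year (January,
April, July, October) before a regime-switch month, and three times per
year (February, June, October) from that month on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PRE_SWITCH_MONTHS = frozenset({1, 4, 7, 10})
POST_SWITCH_MONTHS = frozenset({2, 6, 10})


class ConfigurationError(ValueError):
    """Raised when a scenario or pipeline configuration is invalid."""


@dataclass(frozen=True)
class GeoHierarchy:
    """A district -> province -> country tree.

    Parameters
    ----------
    districts
        District identifiers, in canonical order.
    province_of
        Maps each district id to its province id.
    country_of_province
        Maps each province id to its country id.
    names
        Human-readable unique name per unit (district, province, country).
    """

    districts: tuple[str, ...]
    province_of: dict[str, str]
    country_of_province: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.districts:
            if d not in self.province_of:
                raise ConfigurationError(f"district {d!r} has no province")
        for p in set(self.province_of.values()):
            if p not in self.country_of_province:
                raise ConfigurationError(f"province {p!r} has no country")
        if self.names:
            if len(set(self.names.values())) != len(self.names):
                raise ConfigurationError("unit names must be unique")

    @property
    def provinces(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.districts:
            seen.setdefault(self.province_of[d], None)
        return tuple(seen)

    @property
    def countries(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.provinces:
            seen.setdefault(self.country_of_province[p], None)
        return tuple(seen)

    def country_of(self, district: str) -> str:
        return self.country_of_province[self.province_of[district]]

    def ancestors(self, district: str) -> tuple[str, str]:
        """Return ``(province, country)`` of a district."""
        p = self.province_of[district]
        return p, self.country_of_province[p]

    def members(self, unit: str) -> tuple[str, ...]:
        """Districts contained in ``unit`` (itself, its province, or country)."""
        if unit in self.province_of:
            return (unit,)
        if unit in self.country_of_province:
            return tuple(d for d in self.districts if self.province_of[d] == unit)
        return tuple(d for d in self.districts if self.country_of(d) == unit)

    @property
    def units(self) -> list[tuple[str, str]]:
        """All ``(unit_id, level)`` pairs, districts first."""
        out = [(d, "district") for d in self.districts]
        out += [(p, "province") for p in self.provinces]
        out += [(c, "country") for c in self.countries]
        return out


def match_gazetteer(tokens: list[str], world: "GeoHierarchy") -> list[str]:
    """Optional utility: units whose name occurs in a token sequence.

    Case-insensitive contiguous-token matching of unit names.  The main
    pipeline consumes explicit district-mention lists on article records;
    this helper exists for corpora that only carry raw text tokens.
    """
    hay = [t.lower() for t in tokens]
    hits = []
    for unit, name in world.names.items():
        needle = name.lower().split()
        k = len(needle)
        if any(hay[i : i + k] == needle for i in range(len(hay) - k + 1)):
            hits.append(unit)
    return hits


def _is_reporting_month(m: pd.Period, switch: pd.Period) -> bool:
    if m < switch:
        return m.month in PRE_SWITCH_MONTHS
    return m.month in POST_SWITCH_MONTHS


@dataclass(frozen=True)
class Calendar:
    """Monthly calendar with the phase-reporting schedule.

    ``reporting_periods`` are the period-end months: strictly increasing,
    three months apart before ``regime_switch`` and following the
    {Feb, Jun, Oct} pattern afterwards.
    """

    months: pd.PeriodIndex
    regime_switch: pd.Period

    @classmethod
    def from_range(cls, start: str, n_months: int, regime_switch: str = "2016-01") -> "Calendar":
        if n_months <= 0:
            raise ConfigurationError("n_months must be positive")
        months = pd.period_range(start, periods=n_months, freq="M")
        return cls(months=months, regime_switch=pd.Period(regime_switch, freq="M"))

    @property
    def reporting_periods(self) -> pd.PeriodIndex:
        keep = [m for m in self.months if _is_reporting_month(m, self.regime_switch)]
        return pd.PeriodIndex(keep, freq="M")

    def period_window(self, period_end: pd.Period) -> pd.PeriodIndex:
        """Months covered by the reporting period ending at ``period_end``.

        The window runs from the month after the previous period end through
        ``period_end`` (three months before the regime switch, up to four
        right after it); truncated at the calendar start.
        """
        periods = self.reporting_periods
        pos = periods.get_loc(period_end)
        start = periods[pos - 1] + 1 if pos > 0 else max(self.months[0], period_end - 2)
        start = max(start, self.months[0])
        return pd.period_range(start, period_end, freq="M")
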