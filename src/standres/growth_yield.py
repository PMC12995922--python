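"""Age-indexed yield-table abstraction and competition growth modifiers.

Growth and yield are driven by a classical yield table: for each stand age
(5-year grid, full stocking) the standing volume (m3/ha), the mean diameter
at breast height (cm), and the thinning removal of the step ending at that
age (m3/ha) with its mean DBH.  Yield tables built for management planning
typically omit stands younger than 15 years; :func:`interpolate_young_ages`
fills ages 0/5/10 by linear interpolation between volume 0 at age 0 and the
first tabulated row, so carbon accounting covers young stands too.

Two-cohort stands change competition relative to the even-aged table:

* the young regeneration cohort grows more slowly under the remaining
  canopy — suppression is stronger for larger age differences and for
  smaller gap shares (``suppression_multiplier``);
* the remaining leading cohort enjoys a temporary growth acceleration after
  the canopy opening, scaling with gap share and decaying to 1 within a
  fixed window (``acceleration_multiplier``).

Both multipliers act on volume *increments*, so suppression leaves a
persistent deficit in a cohort's accumulated stock.  The default linear
coefficient values are package defaults satisfying the qualitative
monotonicity constraints; they are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stand_model import STEP_YEARS, Cohort

__all__ = [
    "GrowthTable",
    "GrowthModifiers",
    "interpolate_young_ages",
    "cohort_volume",
    "gross_increment",
    "step_increment",
    "suppression_multiplier",
    "acceleration_multiplier",
]

_COLUMNS = ["age", "standing_volume", "mean_dbh", "thinning_removal", "thinning_dbh"]


@dataclass(frozen=True)
class GrowthTable:
    """Per-age yield-table rows at full stocking.

    ``data`` columns: ``age, standing_volume, mean_dbh, thinning_removal,
    thinning_dbh`` on a 5-year age grid.  ``site_index`` is the mean stand
    height (m) at age 50 the table was parameterized for.
    """

    data: pd.DataFrame
    site_index: float = 21.9

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"growth table is missing columns {missing}")
        if np.any(df["age"].to_numpy() % STEP_YEARS):
            raise ValueError("growth-table ages must lie on the 5-year grid")
        if np.any(df["standing_volume"].to_numpy() < 0):
            raise ValueError("standing volume must be non-negative")
        if np.any(np.diff(df["mean_dbh"].to_numpy()) < 0):
            raise ValueError("mean DBH must be non-decreasing in age")
        object.__setattr__(self, "data", df.sort_values("age").reset_index(drop=True))

    # -- lookups -----------------------------------------------------------
    def _col(self, age: int, col: str) -> float:
        ages = self.data["age"].to_numpy()
        if age < ages[0] or age > ages[-1]:
            raise ValueError(f"age {age} outside table range [{ages[0]}, {ages[-1]}]")
        idx = int(np.searchsorted(ages, age))
        if ages[idx] != age:
            raise ValueError(f"age {age} not on the table grid")
        return float(self.data[col].iloc[idx])

    def volume(self, age: int) -> float:
        return self._col(age, "standing_volume")

    def dbh(self, age: int) -> float:
        return self._col(age, "mean_dbh")

    def thinning(self, age: int) -> float:
        return self._col(age, "thinning_removal")

    def thinning_dbh(self, age: int) -> float:
        return self._col(age, "thinning_dbh")

    @property
    def max_age(self) -> int:
        return int(self.data["age"].iloc[-1])

    @property
    def min_age(self) -> int:
        return int(self.data["age"].iloc[0])

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, site_index: float = 21.9) -> "GrowthTable":
        return cls(pd.read_csv(path), site_index=site_index)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def interpolate_young_ages(table: GrowthTable) -> GrowthTable:
    """Fill ages below the first tabulated row by linear interpolation.

    Volume and DBH are interpolated between ``(age 0, value 0)`` and the
    first tabulated row (which must sit at age 15, the customary first yield
    table entry); thinning removals for the filled ages are 0.  A table
    already starting at age 0 is returned unchanged.
    """
    if table.min_age == 0:
        return table
    if table.min_age != 15:
        raise ValueError(
            f"expected first tabulated age 15, got {table.min_age}; "
            "cannot anchor the young-age interpolation"
        )
    anchor = table.data.iloc[0]
    rows = []
    for age in range(0, table.min_age, STEP_YEARS):
        f = age / table.min_age
        rows.append(
            {
                "age": age,
                "standing_volume": f * anchor["standing_volume"],
                "mean_dbh": f * anchor["mean_dbh"],
                "thinning_removal": 0.0,
                "thinning_dbh": 0.0,
            }
        )
    data = pd.concat([pd.DataFrame(rows), table.data], ignore_index=True)
    return GrowthTable(data, site_index=table.site_index)


@dataclass(frozen=True)
class GrowthModifiers:
    """Competition modifiers for two-cohort stands.

    Suppression of the younger cohort:
    ``m_supp = clamp(1 - (c0 + c1 * (1 - s_gap)) * delta_age, m_min, 1)``.

    Acceleration of the leading cohort after a gap cut:
    ``m_acc = 1 + accel_gain * s_gap * max(0, 1 - years_since_gap / accel_window)``.
    """

    c0: float = 0.004
    c1: float = 0.006
    m_min: float = 0.4
    accel_gain: float = 0.5
    accel_window: float = 15.0

    def suppression(self, delta_age: float, s_gap: float) -> float:
        if delta_age < 0:
            raise ValueError("delta_age must be non-negative")
        raw = 1.0 - (self.c0 + self.c1 * (1.0 - s_gap)) * delta_age
        return float(min(1.0, max(self.m_min, raw)))

    def acceleration(self, s_gap: float, years_since_gap: float) -> float:
        if years_since_gap < 0:
            raise ValueError("years_since_gap must be non-negative")
        decay = max(0.0, 1.0 - years_since_gap / self.accel_window)
        return float(1.0 + self.accel_gain * s_gap * decay)


def suppression_multiplier(
    delta_age: float, s_gap: float, modifiers: Optional[GrowthModifiers] = None
) -> float:
    """Growth-increment multiplier (<= 1) for a suppressed younger cohort."""
    return (modifiers or GrowthModifiers()).suppression(delta_age, s_gap)


def acceleration_multiplier(
    s_gap: float, years_since_gap: float, modifiers: Optional[GrowthModifiers] = None
) -> float:
    """Growth-increment multiplier (>= 1) for the leading cohort after a gap
    cut; exactly 1 once the decay window has elapsed."""
    return (modifiers or GrowthModifiers()).acceleration(s_gap, years_since_gap)


def cohort_volume(table: GrowthTable, cohort: Cohort, modifier_accum: float = 1.0) -> float:
    """Share-scaled, modifier-adjusted standing volume of a cohort (m3 per
    stand hectare).

    ``modifier_accum`` is the cohort's accumulated increment-modifier effect
    expressed as the ratio of its effective stock to the table stock at its
    age; it is 1 for an undisturbed even-aged cohort.
    """
    return cohort.share * modifier_accum * table.volume(cohort.age)


def gross_increment(table: GrowthTable, age: int, step_years: int = STEP_YEARS) -> float:
    """Unmodified gross volume production of the step ``age -> age + step``
    at full stocking: the standing-volume difference plus the thinning
    removal booked at the end of the step (removed wood is still production).
    """
    return (
        table.volume(age + step_years)
        - table.volume(age)
        + table.thinning(age + step_years)
    )


def step_increment(
    table: GrowthTable,
    cohort: Cohort,
    modifier: float = 1.0,
    step_years: int = STEP_YEARS,
) -> float:
    """Modifier-adjusted gross volume increment of one cohort over one step,
    per stand hectare (share-scaled); non-negative."""
    inc = modifier * gross_increment(table, cohort.age, step_years)
    return max(0.0, cohort.share * inc)
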