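"""Comorbidity-adjusted remaining life expectancy.

Raw remaining life expectancy is looked up in a period life table by age, sex
and race. Comorbidity burden then shifts the lookup age upward (the
effective-age method): the encounter's comorbidity weight is banded into
{none, low_medium, high}, each band adds a configured number of years to the
chronological age, and the table is re-entered at the shifted age. Band
offsets are flat in age, which also implements the rule that subjects under
65 receive the 65-year-old's adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Encounter, RACES, SEXES

__all__ = [
    "LifeTable",
    "ComorbidityAdjustment",
    "LifeTableLookupError",
    "read_life_table",
    "default_life_table",
    "comorbidity_band",
    "adjusted_life_expectancy",
    "annotate_cohort",
]

BANDS = ("none", "low_medium", "high")


class LifeTableLookupError(KeyError):
    """Raised when no life-table stratum covers a requested lookup."""


@dataclass
class LifeTable:
    """Remaining life expectancy by (age, sex, race).

    Internally a dict of per-stratum arrays indexed by age. Races absent from
    the table fall back to the ``"all"`` stratum when present.
    """

    strata: dict[tuple[str, str], dict[int, float]]

    def __post_init__(self) -> None:
        for (sex, race), by_age in self.strata.items():
            ages = sorted(by_age)
            ex = [by_age[a] for a in ages]
            if any(v < 0 for v in ex):
                raise ValueError(f"negative life expectancy in stratum ({sex}, {race})")
            adult = [(a, v) for a, v in zip(ages, ex) if a >= 18]
            if any(b[1] > a[1] + 1e-9 for a, b in zip(adult, adult[1:])):
                warnings.warn(
                    f"life expectancy not non-increasing in age for ({sex}, {race})",
                    stacklevel=2,
                )

    @property
    def max_age(self) -> int:
        return max(max(by_age) for by_age in self.strata.values())

    def lookup(self, age: int, sex: str, race: str) -> float:
        key = (sex, race)
        if key not in self.strata:
            key = (sex, "all")
        if key not in self.strata:
            raise LifeTableLookupError(
                f"no life-table stratum for age={age}, sex={sex!r}, race={race!r}"
            )
        by_age = self.strata[key]
        clamped = min(max(age, min(by_age)), max(by_age))
        if clamped not in by_age:
            raise LifeTableLookupError(
                f"no life-table row for age={clamped}, sex={sex!r}, race={race!r}"
            )
        return by_age[clamped]


def read_life_table(path) -> LifeTable:
    """Read a life-table CSV with columns age, sex, race, ex."""
    df = pd.read_csv(path)
    required = {"age", "sex", "race", "ex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"life table missing column(s): {', '.join(sorted(missing))}")
    strata: dict[tuple[str, str], dict[int, float]] = {}
    for rec in df.to_dict("records"):
        key = (str(rec["sex"]), str(rec["race"]))
        strata.setdefault(key, {})[int(rec["age"])] = float(rec["ex"])
    return LifeTable(strata)


# Terminal-age parameters of the bundled synthetic table. These are smooth,
# monotone placeholders — NOT official vital-statistics values. Supply a real
# life-table CSV for substantive analyses.
_SYNTH_TERMINAL_AGE = {"male": 81.0, "female": 86.0}
_SYNTH_RACE_SHIFT = {
    "white_nh": 0.0,
    "black_nh": -2.5,
    "hispanic": 2.0,
    "aapi_nh": 3.0,
    "aian_nh": -4.0,
    "multi_nh": 0.0,
    "unknown": 0.0,
    "all": 0.0,
}


def default_life_table(max_age: int = 100) -> LifeTable:
    """Bundled synthetic life table covering ages 18-100 for every stratum."""
    strata: dict[tuple[str, str], dict[int, float]] = {}
    ages = np.arange(18, max_age + 1)
    for sex in SEXES:
        for race in (*RACES, "all"):
            terminal = _SYNTH_TERMINAL_AGE[sex] + _SYNTH_RACE_SHIFT[race]
            # Linear decline toward the terminal age with a slowly decaying
            # old-age tail keeps ex positive and strictly decreasing.
            ex = np.maximum(terminal - ages, 0.0) * 0.92 + 6.0 * np.exp(
                -(ages - 18.0) / 25.0
            ) + 1.5
            strata[(sex, race)] = {int(a): float(e) for a, e in zip(ages, ex)}
    return LifeTable(strata)


def write_life_table(table: LifeTable, path) -> None:
    rows = [
        {"age": age, "sex": sex, "race": race, "ex": ex}
        for (sex, race), by_age in table.strata.items()
        for age, ex in sorted(by_age.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ComorbidityAdjustment:
    """Comorbidity banding thresholds and per-band age offsets.

    ``none_max`` is the largest weight still counted as "none";
    ``high_min`` the smallest counted as "high"; everything between is
    "low_medium". Offsets are years added to the lookup age. Defaults
    (0/3/7 years) are configurable placeholders.
    """

    none_max: int = 0
    high_min: int = 12
    age_offset: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "low_medium": 3.0, "high": 7.0}
    )

    def __post_init__(self) -> None:
        if set(self.age_offset) != set(BANDS):
            raise ValueError(f"age_offset must cover exactly {BANDS}")
        offsets = [self.age_offset[b] for b in BANDS]
        if offsets[0] != 0:
            raise ValueError("age_offset['none'] must be 0")
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("age offsets must be non-decreasing across bands")

    @classmethod
    def from_yaml(cls, path) -> "ComorbidityAdjustment":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "none_max" in raw:
            kwargs["none_max"] = int(raw["none_max"])
        if "high_min" in raw:
            kwargs["high_min"] = int(raw["high_min"])
        if "age_offset" in raw:
            kwargs["age_offset"] = {k: float(v) for k, v in raw["age_offset"].items()}
        return cls(**kwargs)

    def band(self, weight: int) -> str:
        if weight <= self.none_max:
            return "none"
        if weight >= self.high_min:
            return "high"
        return "low_medium"


def comorbidity_band(weight: int, adj: ComorbidityAdjustment | None = None) -> str:
    """Band a comorbidity weight into none / low_medium / high."""
    return (adj or ComorbidityAdjustment()).band(weight)


def adjusted_life_expectancy(
    e: Encounter,
    table: LifeTable,
    adj: ComorbidityAdjustment | None = None,
) -> float:
    """Life expectancy at the comorbidity-shifted effective age.

    The effective age is chronological age plus the band's offset, clamped to
    the table's maximum age.
    """
    adj = adj or ComorbidityAdjustment()
    band = adj.band(e.elixhauser)
    effective_age = int(round(e.age + adj.age_offset[band]))
    effective_age = min(effective_age, table.max_age)
    return table.lookup(effective_age, e.sex, e.race_ethnicity)


def annotate_cohort(
    cohort: Sequence[Encounter],
    table: LifeTable | None = None,
    adj: ComorbidityAdjustment | None = None,
) -> list[Encounter]:
    """Fill ``life_expectancy`` on every encounter (returns the same objects).

    Non-survivors are annotated too; their years are only counted downstream
    when an allocated encounter actually survives.
    """
    table = table or default_life_table()
    for enc in cohort:
        try:
            enc.life_expectancy = adjusted_life_expectancy(enc, table, adj)
        except LifeTableLookupError as exc:
            raise LifeTableLookupError(
                f"encounter {enc.encounter_id}: {exc.args[0]}"
            ) from exc
    return list(cohort)
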