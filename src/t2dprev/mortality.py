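"""Life-table handling and age-band mortality for the cohort model.

The model uses coarse mortality: annual death probabilities are pooled
into four age bands (<35, 35-64, 65-74, 75 and over) per sex.  Two
quantities drive deaths:

``mr``      the annual probability of dying of anything other than
            diabetes, applied to every alive state;
``t2d2d``   the additional annual probability that a person with
            diagnosed T2D dies of their diabetes.

``mr`` comes from a national life table after subtracting diabetes-
attributable deaths.  ``t2d2d`` is derived from the share of all-cause
deaths attributable to diabetes: that share of the all-cause rate is an
event rate over the whole population, so dividing by the band's diabetes
prevalence converts it to a per-person-with-T2D probability (capped so
that mr + t2d2d never exceeds 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import SEXES

__all__ = [
    "BANDS",
    "BAND_BOUNDS",
    "band_for_age",
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "MortalityModel",
    "mr_from_life_table",
    "attributable_fraction_from_life_table",
    "all_cause_rate_from_life_table",
    "t2d2d_from_fraction",
    "mortality_from_life_table",
]

BANDS = ("<35", "35-64", "65-74", "75+")
# half-open [lo, hi): ages 35, 65 and 75 belong to the upper band
BAND_BOUNDS = {"<35": (0, 35), "35-64": (35, 65), "65-74": (65, 75), "75+": (75, 200)}

LIFE_TABLE_COLUMNS = ["age", "sex", "population", "deaths_total", "deaths_diabetes"]


def band_for_age(age: int | float) -> str:
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age < 35:
        return "<35"
    if age < 65:
        return "35-64"
    if age < 75:
        return "65-74"
    return "75+"


@dataclass
class LifeTable:
    """Single-age mortality counts by sex.

    Wraps a DataFrame with columns age, sex, population, deaths_total,
    deaths_diabetes.  Counts may be fractional (synthetic tables are
    expectation-valued); validity requires population > 0 and
    0 <= deaths_diabetes <= deaths_total <= population in every row.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in LIFE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"life table is missing columns: {missing}")
        self.data = df = df[LIFE_TABLE_COLUMNS].copy()
        problems = []
        if (df["population"] <= 0).any():
            problems.append("population must be positive in every row")
        if (df["deaths_total"] < df["deaths_diabetes"]).any():
            problems.append("deaths_diabetes exceeds deaths_total in some row")
        if (df["deaths_diabetes"] < 0).any():
            problems.append("deaths_diabetes must be non-negative")
        if (df["deaths_total"] > df["population"]).any():
            problems.append("deaths_total exceeds population in some row")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            problems.append(f"unknown sex values {sorted(bad_sex)}; expected {SEXES}")
        if problems:
            raise ValueError("invalid life table: " + "; ".join(problems))

    def with_bands(self) -> pd.DataFrame:
        df = self.data.copy()
        df["band"] = [band_for_age(a) for a in df["age"]]
        return df


def read_life_table(path: str | Path) -> LifeTable:
    """Read the CSV dialect: header row, columns age, sex, population,
    deaths_total, deaths_diabetes, UTF-8."""
    df = pd.read_csv(path, encoding="utf-8")
    return LifeTable(df)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, encoding="utf-8")


@dataclass
class MortalityModel:
    """Per-(sex, band) non-diabetes and diabetes-attributable death probabilities."""

    mr: dict[tuple[str, str], float]
    t2d2d: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for (sex, band), v in self.mr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mr[{sex}, {band}] = {v} outside [0, 1]")
        for key, v in self.t2d2d.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"t2d2d[{key}] = {v} outside [0, 1]")
            if self.mr.get(key, 0.0) + v > 1.0 + 1e-12:
                raise ValueError(f"mr + t2d2d exceeds 1 for {key}")

    @classmethod
    def zero(cls) -> "MortalityModel":
        """An immortal cohort; useful for conservation and annuity checks."""
        return cls(mr={(s, b): 0.0 for s in SEXES for b in BANDS}, t2d2d={})

    @classmethod
    def uniform(cls, mr: float, t2d2d: float = 0.0) -> "MortalityModel":
        return cls(
            mr={(s, b): mr for s in SEXES for b in BANDS},
            t2d2d={(s, b): t2d2d for s in SEXES for b in BANDS},
        )

    def death_probabilities(self, age: int | float, sex: str) -> tuple[float, float]:
        """(non-diabetes death prob, T2D-state death prob) at this age and sex.

        Ages beyond the last band reuse the 75+ values.  The T2D state adds
        the diabetes-attributable excess on top of background mortality.
        """
        band = band_for_age(age)
        mr = self.mr[(sex, band)]
        excess = self.t2d2d.get((sex, band), 0.0)
        return mr, min(1.0, mr + excess)


def _band_aggregate(table: LifeTable) -> pd.DataFrame:
    df = table.with_bands()
    agg = df.groupby(["sex", "band"], as_index=False)[
        ["population", "deaths_total", "deaths_diabetes"]
    ].sum()
    return agg


def mr_from_life_table(table: LifeTable) -> dict[tuple[str, str], float]:
    """Non-diabetes death probability per (sex, band).

    Diabetes-attributable deaths are subtracted from total deaths before
    dividing by the band population, so mr reflects dying of anything else.
    Every band present must have positive population (guaranteed row-wise
    by LifeTable validation); a band entirely absent from the table for a
    sex raises, since the model needs all four bands.
    """
    agg = _band_aggregate(table)
    out: dict[tuple[str, str], float] = {}
    sexes = sorted(set(table.data["sex"]))
    for sex in sexes:
        for band in BANDS:
            sel = agg[(agg["sex"] == sex) & (agg["band"] == band)]
            if sel.empty:
                raise ValueError(f"life table has no rows for sex={sex!r}, band={band!r}")
            pop = float(sel["population"].iloc[0])
            non_diab = float(sel["deaths_total"].iloc[0] - sel["deaths_diabetes"].iloc[0])
            out[(sex, band)] = non_diab / pop
    return out


def attributable_fraction_from_life_table(table: LifeTable) -> dict[tuple[str, str], float]:
    """Share of all-cause deaths attributable to diabetes per (sex, band)."""
    agg = _band_aggregate(table)
    out = {}
    for _, row in agg.iterrows():
        total = float(row["deaths_total"])
        out[(row["sex"], row["band"])] = (
            float(row["deaths_diabetes"]) / total if total > 0 else 0.0
        )
    return out


def all_cause_rate_from_life_table(table: LifeTable) -> dict[tuple[str, str], float]:
    agg = _band_aggregate(table)
    return {
        (row["sex"], row["band"]): float(row["deaths_total"]) / float(row["population"])
        for _, row in agg.iterrows()
    }


def t2d2d_from_fraction(
    attributable_fraction: float,
    all_cause_rate: float,
    diabetes_prevalence: float,
    mr: float = 0.0,
) -> float:
    """Per-person-with-T2D annual diabetes death probability.

    The attributable fraction times the all-cause rate is the population
    rate of diabetes deaths; those deaths occur among the diabetic
    sub-population only, so dividing by prevalence gives the per-diabetic
    probability.  Capped at 1 - mr so total mortality stays a probability.
    """
    if not 0.0 <= attributable_fraction < 1.0:
        raise ValueError(f"attributable fraction must lie in [0, 1), got {attributable_fraction}")
    if diabetes_prevalence <= 0.0:
        if attributable_fraction == 0.0:
            return 0.0
        raise ValueError("diabetes prevalence must be positive when the fraction is > 0")
    value = attributable_fraction * all_cause_rate / diabetes_prevalence
    if value < 0.0:
        raise ValueError(f"negative t2d2d: {value}")
    return min(value, 1.0 - mr)


def mortality_from_life_table(
    table: LifeTable,
    diabetes_prevalence: dict[tuple[str, str], float] | None = None,
    t2d2d_override: dict[tuple[str, str], float] | None = None,
) -> MortalityModel:
    """Build the full MortalityModel from a life table.

    Two conventions are supported for turning the diabetes-attributable
    death share into the T2D excess probability:

    * ``diabetes_prevalence`` given — the attributable share of the
      all-cause rate is divided by the band's diabetes prevalence, giving
      a per-person-with-T2D probability (dimensionally strict; large
      excess).
    * ``diabetes_prevalence=None`` (default) — the attributable share of
      the all-cause rate is used directly as t2d2d, i.e. the excess is
      read as an add-on to the state's annual death probability.  This is
      the convention that reproduces the published incremental results.

    Explicit ``t2d2d_override`` entries win over either derivation.
    """
    mr = mr_from_life_table(table)
    fractions = attributable_fraction_from_life_table(table)
    rates = all_cause_rate_from_life_table(table)
    t2d2d = {}
    for key, m in mr.items():
        if t2d2d_override and key in t2d2d_override:
            t2d2d[key] = min(t2d2d_override[key], 1.0 - m)
            continue
        frac = fractions.get(key, 0.0)
        if frac <= 0.0:
            t2d2d[key] = 0.0
        elif diabetes_prevalence is None:
            t2d2d[key] = min(frac * rates[key], 1.0 - m)
        else:
            t2d2d[key] = t2d2d_from_fraction(
                frac, rates[key], diabetes_prevalence.get(key, 0.0), mr=m
            )
    return MortalityModel(mr=mr, t2d2d=t2d2d)
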