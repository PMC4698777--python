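"""Age-indexed all-cause mortality, real or synthetic.

The cohort model needs an annual background mortality rate for every age
the cohort can reach.  A national life table can be supplied as CSV
(header ``age,mortality_rate``, one row per integer age, rates in deaths
per person-year).  When no table is available, :func:`generate_life_table`
synthesises one from the Gompertz-Makeham law of adult mortality,

    rate(x) = makeham + gompertz_a * exp(gompertz_b * x),

whose default coefficients give mortality of the order seen in national
tables for an industrialised population (about 0.3% per year at age 40,
0.8% at 50, 2% in the early 60s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .parameters import ParameterError, rate_to_probability

__all__ = ["LifeTable", "GompertzMakehamParams", "generate_life_table"]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Coefficients of the Gompertz-Makeham mortality hazard.

    ``makeham`` is the age-independent background rate (per person-year),
    ``gompertz_a`` the senescent rate scale (per person-year) and
    ``gompertz_b`` the exponential slope (per year of age).
    """

    makeham: float = 0.001
    gompertz_a: float = 0.0001
    gompertz_b: float = 0.085

    def __post_init__(self) -> None:
        for name in ("makeham", "gompertz_a", "gompertz_b"):
            if getattr(self, name) < 0:
                raise ParameterError(name, getattr(self, name), "must be >= 0")

    def rate(self, age: float) -> float:
        return self.makeham + self.gompertz_a * math.exp(self.gompertz_b * age)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality rates on a contiguous integer age grid."""

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.size == 0:
            raise ParameterError("ages", ages, "life table must be non-empty")
        if ages.size != rates.size:
            raise ParameterError("rates", rates.size, "ages and rates must align")
        if not np.all(np.diff(ages) == 1):
            raise ParameterError("ages", ages, "ages must increase in steps of 1 year")
        if np.any(rates < 0):
            raise ParameterError("mortality_rate", rates.min(), "rates must be >= 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def covers(self, start_age: float, end_age: float) -> bool:
        return self.min_age <= math.floor(start_age) and math.floor(end_age) <= self.max_age

    def rate_at(self, age: float) -> float:
        """Mortality rate for the single-year age band containing ``age``."""
        idx = math.floor(age) - self.min_age
        if not 0 <= idx < self.ages.size:
            raise ParameterError(
                "age",
                age,
                f"outside life-table support [{self.min_age}, {self.max_age}]; "
                "extend the table",
            )
        return float(self.rates[idx])

    def death_probability(self, age: float) -> float:
        """Annual death probability at ``age`` via the constant-hazard identity."""
        return rate_to_probability(self.rate_at(age))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mortality_rate": self.rates})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "mortality_rate"} - set(df.columns)
        if missing:
            raise ParameterError("life_table", str(path), f"missing column(s) {sorted(missing)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["mortality_rate"].to_numpy())


def generate_life_table(
    params: GompertzMakehamParams | None = None,
    age_range: Iterable[int] = range(0, 111),
) -> LifeTable:
    """Deterministically synthesise a life table from the Gompertz-Makeham law."""
    gm = params if params is not None else GompertzMakehamParams()
    ages = np.asarray(list(age_range), dtype=int)
    if ages.size == 0:
        raise ParameterError("age_range", age_range, "must be non-empty")
    rates = gm.makeham + gm.gompertz_a * np.exp(gm.gompertz_b * ages.astype(float))
    return LifeTable(ages, rates)
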