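"""Age-indexed background mortality.

The model needs an all-cause mortality schedule for Chinese adults.  The
published national yearbook rates are not redistributable here, so the
default table is a synthetic Gompertz-Makeham hazard

    mu(age) = a + b * exp(c * age)

with the Makeham floor ``a`` and the Gompertz slope ``c`` fixed on standard
demographic grounds (a = 2e-4 per year, a low accident/background floor for
a modern population; c = 0.10, an adult mortality doubling time of about
seven years) and the scale ``b`` calibrated by bisection so that remaining
life expectancy at age 45 equals 35 years — the one quantitative anchor the
source analysis states for its population.  Users can substitute a real
table via a two-column CSV (``age,annual_mortality_rate``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import CalibrationError

DEFAULT_AGE_SPAN = (30, 110)
DEFAULT_MAKEHAM = 2e-4
DEFAULT_GOMPERTZ_SHAPE = 0.10
LIFE_EXPECTANCY_ANCHOR = 35.0  # remaining years at age 45
ANCHOR_AGE = 45.0


@dataclass(frozen=True)
class GompertzMakehamParams:
    """hazard(age) = makeham + gompertz_scale * exp(gompertz_shape * age)"""

    makeham: float = DEFAULT_MAKEHAM
    gompertz_scale: float = 1e-5
    gompertz_shape: float = DEFAULT_GOMPERTZ_SHAPE

    def hazard(self, age: float) -> float:
        return self.makeham + self.gompertz_scale * math.exp(self.gompertz_shape * age)

    def validate(self) -> None:
        if self.makeham < 0:
            raise ValueError(f"makeham baseline must be >= 0, got {self.makeham}")
        if self.gompertz_scale < 0:
            raise ValueError(
                f"gompertz_scale must be >= 0, got {self.gompertz_scale}"
            )
        if self.gompertz_scale > 0 and self.gompertz_shape <= 0:
            raise ValueError(
                f"gompertz_shape must be > 0, got {self.gompertz_shape}"
            )
        if self.makeham == 0 and self.gompertz_scale == 0:
            raise ValueError("hazard is identically zero")


class LifeTable:
    """Annual all-cause mortality rates at integer ages.

    Lookups floor the queried age; queries outside the covered span raise.
    Rates are hazards per person-year (>= 0; zero rates are admitted so that
    degenerate no-mortality tables can be constructed for verification).
    """

    def __init__(self, ages, annual_rates):
        ages = np.asarray(ages, dtype=int)
        rates = np.asarray(annual_rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape or ages.size == 0:
            raise ValueError("ages and annual_rates must be matching 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be consecutive integers")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("annual rates must be finite and >= 0")
        self.ages = ages
        self.annual_rates = rates

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_mortality(self, age: float) -> float:
        """Annual all-cause mortality rate at floor(age)."""
        idx = math.floor(age) - self.min_age
        if idx < 0 or idx >= self.ages.size:
            raise ValueError(
                f"age {age} outside life-table span "
                f"[{self.min_age}, {self.max_age}]"
            )
        return float(self.annual_rates[idx])

    def covers(self, start_age: float, horizon: float) -> bool:
        return self.min_age <= start_age and start_age + horizon - 1e-9 <= self.max_age + 1

    def life_expectancy(self, from_age: float) -> float:
        """Remaining life expectancy in years from ``from_age``.

        Upper Riemann sum of the yearly survival curve (each year is
        credited at its start), truncated at the end of the table:
        sum over k >= 0 of S(k) with S(0) = 1 and S accumulating
        exp(-rate) per year.
        """
        start = math.floor(from_age)
        if start < self.min_age or start > self.max_age:
            raise ValueError(
                f"age {from_age} outside life-table span "
                f"[{self.min_age}, {self.max_age}]"
            )
        surv = np.exp(-np.cumsum(self.annual_rates[start - self.min_age:]))
        return float(1.0 + surv.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "annual_mortality_rate": self.annual_rates}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_lifetable(path) -> LifeTable:
    df = pd.read_csv(path)
    expected = ["age", "annual_mortality_rate"]
    if list(df.columns) != expected:
        raise ValueError(f"life-table CSV must have columns {expected}, got {list(df.columns)}")
    return LifeTable(df["age"].to_numpy(), df["annual_mortality_rate"].to_numpy())


def annual_mortality(lt: LifeTable, age: float) -> float:
    return lt.annual_mortality(age)


def life_expectancy(lt: LifeTable, from_age: float) -> float:
    return lt.life_expectancy(from_age)


def make_synthetic_lifetable(
    params: GompertzMakehamParams,
    age_span: tuple[int, int] = DEFAULT_AGE_SPAN,
) -> LifeTable:
    """Evaluate the Gompertz-Makeham hazard at integer ages."""
    params.validate()
    lo, hi = int(age_span[0]), int(age_span[1])
    if hi <= lo:
        raise ValueError(f"empty age span {age_span}")
    ages = np.arange(lo, hi + 1)
    rates = params.makeham + params.gompertz_scale * np.exp(
        params.gompertz_shape * ages
    )
    if np.any(rates <= 0):
        raise ValueError("synthetic hazard must be strictly positive")
    return LifeTable(ages, rates)


def calibrate_to_life_expectancy(
    target_le: float,
    from_age: float = ANCHOR_AGE,
    shape_prior: GompertzMakehamParams | None = None,
    age_span: tuple[int, int] = DEFAULT_AGE_SPAN,
    tol: float = 0.05,
) -> GompertzMakehamParams:
    """Find the Gompertz scale ``b`` matching a life-expectancy target.

    Life expectancy is strictly decreasing in ``b``, so a log-scale
    bisection converges; the Makeham floor and Gompertz slope are kept at
    the prior's values.  Raises :class:`CalibrationError` when no bracket
    exists (target unreachable given the floor or the table truncation).
    """
    prior = shape_prior or GompertzMakehamParams()
    prior.validate()

    def le_for(b: float) -> float:
        p = GompertzMakehamParams(prior.makeham, b, prior.gompertz_shape)
        return make_synthetic_lifetable(p, age_span).life_expectancy(from_age)

    lo, hi = 1e-12, 1e-1
    if not (le_for(hi) <= target_le <= le_for(lo)):
        raise CalibrationError(
            f"life expectancy target {target_le} at age {from_age} is outside "
            f"the attainable range [{le_for(hi):.2f}, {le_for(lo):.2f}] years"
        )
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if le_for(mid) > target_le:
            lo = mid
        else:
            hi = mid
        if abs(le_for(mid) - target_le) <= tol:
            return GompertzMakehamParams(prior.makeham, mid, prior.gompertz_shape)
    raise CalibrationError("bisection failed to converge")  # pragma: no cover


@lru_cache(maxsize=1)
def default_lifetable() -> LifeTable:
    """The calibrated synthetic default table (LE at 45 = 35 years)."""
    params = calibrate_to_life_expectancy(LIFE_EXPECTANCY_ANCHOR, ANCHOR_AGE)
    return make_synthetic_lifetable(params)
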