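"""National budget-impact projection with uptake and implementation costs.

Each calendar year a new cohort of eligible patients (national incidence x
uptake) receives closure.  Every treated cohort then follows the cohort
model's undiscounted incremental cost trajectory (closure minus medical
therapy): a net outlay in its first year — device, procedure,
hospitalization — followed by annual net savings from prevented strokes.
Stacking the cohorts and adding any programme implementation costs gives
the payer's annual and cumulative net position; the break-even year is the
first year the cumulative net position turns non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import run_cohort
from .lifetable import LifeTable
from .parameters import ParameterSet


def default_uptake(horizon_years: int = 10) -> tuple[float, ...]:
    """50% uptake in year 1 rising linearly to 80% by year 5, then flat."""
    ramp = np.linspace(0.5, 0.8, 5)
    out = np.full(horizon_years, 0.8)
    out[: min(5, horizon_years)] = ramp[:horizon_years]
    return tuple(float(x) for x in out)


def default_implementation(horizon_years: int = 10) -> tuple[float, ...]:
    """US$2 million per year for the first three programme years."""
    out = np.zeros(horizon_years)
    out[: min(3, horizon_years)] = 2_000_000.0
    return tuple(float(x) for x in out)


@dataclass(frozen=True)
class BudgetSettings:
    eligible_per_year: float = 4200.0
    horizon_years: int = 10
    uptake_by_year: tuple[float, ...] = field(default_factory=default_uptake)
    implementation_cost_by_year: tuple[float, ...] = field(
        default_factory=default_implementation
    )
    closure_total: float = 6635.0

    def validate(self) -> None:
        if self.eligible_per_year < 0:
            raise ValueError("eligible_per_year must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if any(not 0.0 <= u <= 1.0 for u in self.uptake_by_year):
            raise ValueError("uptake values must lie in [0, 1]")
        if len(self.uptake_by_year) < self.horizon_years:
            raise ValueError("uptake schedule shorter than horizon")
        if len(self.implementation_cost_by_year) < self.horizon_years:
            raise ValueError("implementation schedule shorter than horizon")


@dataclass(frozen=True)
class BudgetResult:
    """All series are per calendar year, USD; savings are positive."""

    year: tuple[int, ...]
    gross_outlay: tuple[float, ...]  # device + procedure spending that year
    offsets: tuple[float, ...]  # savings realized that year by all cohorts
    implementation: tuple[float, ...]
    annual_net: tuple[float, ...]  # offsets - outlay - implementation
    cumulative_net: tuple[float, ...]
    break_even_year: int | None  # first year cumulative_net >= 0


def per_patient_cost_slices(
    p: ParameterSet, lt: LifeTable, years: int
) -> np.ndarray:
    """Undiscounted incremental cost (closure - medical) by year on
    treatment, from the cohort model; slice 0 includes the procedure."""
    closure = run_cohort("closure", p, lt)
    medical = run_cohort("medical", p, lt)
    diff = closure.cycle_cost_undiscounted - medical.cycle_cost_undiscounted
    per_year = round(1.0 / p.settings.cycle_length)
    n_years = diff.size // per_year
    slices = diff[: n_years * per_year].reshape(n_years, per_year).sum(axis=1)
    if years > n_years:
        raise ValueError(
            f"budget horizon {years} y exceeds model horizon {n_years} y"
        )
    return slices[:years]


def project(
    settings: BudgetSettings,
    per_patient_slices: np.ndarray | None = None,
    p: ParameterSet | None = None,
    lt: LifeTable | None = None,
) -> BudgetResult:
    """Stack treated cohorts over the budget horizon.

    ``per_patient_slices`` (incremental cost per patient by year on
    treatment) may be given directly or computed from a parameter set and
    life table.
    """
    settings.validate()
    T = settings.horizon_years
    if per_patient_slices is None:
        if p is None or lt is None:
            raise ValueError("need per_patient_slices or (p, lt)")
        per_patient_slices = per_patient_cost_slices(p, lt, T)
    slices = np.asarray(per_patient_slices, dtype=float)[:T]

    cohort_sizes = settings.eligible_per_year * np.asarray(
        settings.uptake_by_year[:T]
    )
    outlay = cohort_sizes * settings.closure_total
    impl = np.asarray(settings.implementation_cost_by_year[:T], dtype=float)

    net_cost = np.zeros(T)  # incremental spending incl. implementation
    for start in range(T):
        n_pat = cohort_sizes[start]
        if n_pat == 0:
            continue
        span = min(slices.size, T - start)
        net_cost[start:start + span] += n_pat * slices[:span]
    net_cost += impl

    offsets = outlay + impl - net_cost
    annual_net = -net_cost
    cumulative = np.cumsum(annual_net)
    break_even = None
    for i, v in enumerate(cumulative):
        if v >= 0 and (outlay[: i + 1].sum() > 0 or impl[: i + 1].sum() > 0):
            break_even = i + 1
            break

    return BudgetResult(
        year=tuple(range(1, T + 1)),
        gross_outlay=tuple(float(x) for x in outlay),
        offsets=tuple(float(x) for x in offsets),
        implementation=tuple(float(x) for x in impl),
        annual_net=tuple(float(x) for x in annual_net),
        cumulative_net=tuple(float(x) for x in cumulative),
        break_even_year=break_even,
    )
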