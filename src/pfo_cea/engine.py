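"""Cohort simulation: cycle loop, discounting, accrual, event counting.

The cohort enters in the stable state (in the closure arm, minus the small
procedure-mortality mass, which is moved to DEAD before any transitions)
and is pushed through the 3-month transition matrices over the horizon.

Half-cycle correction is trapezoidal: recurring accruals value the mean of
start- and end-of-cycle occupancy, which for constant payoffs equals the
classical half-weighting of the first and last cycles.  A person who flows
from state i to state j therefore contributes (u_i + u_j)/2 for the cycle;
occupants who experience a recurrent stroke in a cycle are instead valued
at the acute event utility (0.20 absolute by default; a configuration
toggle reinterprets it as a decrement) for that cycle.  Discounting is
evaluated at cycle midpoints; one-time entry costs (the procedure package
and its disutility) are undiscounted at time zero.

Cost accrual per cycle:
  * stable, medical arm  — quarterly share of the annual medical-therapy
    cost, the antithrombotic regimen (monthly price x 3), and the
    high-distress psychological cost at its prevalence;
  * stable, closure arm  — aspirin for the first post-procedure year only;
  * post-stroke states   — quarterly care cost plus the depression/anxiety
    psychological cost at its prevalence (both arms; the medical arm also
    continues its regimen);
  * acute event costs in the event cycle (fatal events are charged once at
    the moderate-to-severe acute cost);
  * the full procedure package at cycle 0 of the closure arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .lifetable import LifeTable
from .parameters import ParameterSet
from .transitions import build_matrix, rate_to_prob, recurrence_rate

_MONTHLY = {"aspirin": "monthly_aspirin", "clopidogrel": "monthly_clopidogrel",
            "warfarin": "monthly_warfarin"}


def discount_factor(rate: float, time: float) -> float:
    """Annual compound discounting, (1 + rate) ** (-time)."""
    if rate < 0 or time < 0:
        raise ValueError("rate and time must be >= 0")
    return (1.0 + rate) ** (-time)


@dataclass
class CohortTrace:
    """Per-cycle record of one strategy arm."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, 4) state proportions
    cycle_cost: np.ndarray  # discounted USD accrued in each cycle
    cycle_cost_undiscounted: np.ndarray
    cycle_qaly: np.ndarray  # discounted QALYs accrued in each cycle
    cycle_life_years: np.ndarray  # undiscounted alive-years per cycle
    events: np.ndarray  # (n_cycles, 3) minor / moderate-severe / fatal
    stroke_free: np.ndarray  # P(no recurrent stroke by year y), y = 0..horizon
    start_age: float
    cycle_length: float
    discount_rate: float
    half_cycle_correction: bool

    @property
    def n_cycles(self) -> int:
        return self.events.shape[0]

    @property
    def settings_key(self) -> tuple:
        return (self.start_age, self.n_cycles, self.cycle_length,
                self.discount_rate, self.half_cycle_correction)

    def to_frame(self):
        import pandas as pd

        k = np.arange(self.n_cycles)
        return pd.DataFrame({
            "cycle": k,
            "age": self.start_age + k * self.cycle_length,
            "stable": self.occupancy[:-1, 0],
            "post_minor": self.occupancy[:-1, 1],
            "post_modsev": self.occupancy[:-1, 2],
            "dead": self.occupancy[:-1, 3],
            "cycle_cost": self.cycle_cost,
            "cycle_qaly": self.cycle_qaly,
            "events_minor": self.events[:, 0],
            "events_modsev": self.events[:, 1],
            "events_fatal": self.events[:, 2],
        })


@dataclass(frozen=True)
class StrategyResult:
    """Totals of one arm: discounted economics plus clinical outcomes."""

    strategy: str
    total_cost: float
    total_cost_undiscounted: float
    total_qaly: float
    life_years: float
    strokes_minor: float
    strokes_moderate_severe: float
    strokes_fatal: float
    strokes_total: float
    stroke_free_survival: dict[int, float]
    settings_key: tuple = ()


def run_cohort(strategy: str, p: ParameterSet, lt: LifeTable) -> CohortTrace:
    """Simulate one strategy arm over the model horizon."""
    s = p.settings
    cl = s.cycle_length
    n_cycles = round(s.horizon / cl)
    if abs(n_cycles * cl - s.horizon) > 1e-9 or n_cycles < 1:
        raise ModelError(f"horizon {s.horizon} is not a whole number of cycles")
    if not lt.covers(s.start_age, s.horizon):
        raise ModelError(
            f"life table [{lt.min_age}, {lt.max_age}] does not cover "
            f"ages [{s.start_age}, {s.start_age + s.horizon}]"
        )

    closure = strategy == "closure"
    q = rate_to_prob(recurrence_rate(p, strategy), cl)
    s_min, s_mod, s_fat = p.clinical.severity_split
    hcc = s.half_cycle_correction
    r = s.discount_rate
    c, u = p.costs, p.utilities
    med_cost = getattr(c, _MONTHLY[s.regimen]) * 3.0
    aspirin_cycles = round(s.closure_antiplatelet_years / cl)
    dep_cost = c.quarterly_psych_depression * s.depression_prevalence if s.psych_costs else 0.0
    dis_cost = c.quarterly_psych_distress * s.distress_prevalence if s.psych_costs else 0.0
    af_decr_cycles = 4 if (closure and s.closure_first_year_utility_decrement) else 0

    occ = np.zeros((n_cycles + 1, 4))
    cost_d = np.zeros(n_cycles)
    cost_u = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    lyrs = np.zeros(n_cycles)
    events = np.zeros((n_cycles, 3))
    n_years = round(s.horizon)
    stroke_free = np.ones(n_years + 1)

    pm = p.clinical.procedure_mortality if closure else 0.0
    occ[0] = (1.0 - pm, 0.0, 0.0, pm)

    if closure:
        upfront = c.closure_total + s.closure_extra_upfront_cost
        cost_d[0] += upfront
        cost_u[0] += upfront
        qaly[0] -= u.procedure_disutility * cl  # procedure cycle decrement

    matrix_cache: dict[int, tuple] = {}
    never_stroked = occ[0, 0]
    cum_first_events = 0.0
    prev_dead = occ[0, 3]

    for k in range(n_cycles):
        age = s.start_age + k * cl
        year = math.floor(age)
        rows = matrix_cache.get(year)
        if rows is None:
            mat = build_matrix(strategy, age, p, lt, k)
            rows = tuple(tuple(float(x) for x in row) for row in mat)
            matrix_cache[year] = rows
        m = rate_to_prob(lt.annual_mortality(age), cl)

        s0, s1, s2, s3 = occ[k]
        e0 = (rows[0][0] * s0,
              rows[0][1] * s0 + rows[1][1] * s1,
              rows[0][2] * s0 + rows[1][2] * s1 + rows[2][2] * s2,
              rows[0][3] * s0 + rows[1][3] * s1 + rows[2][3] * s2 + s3)
        occ[k + 1] = e0

        total = e0[0] + e0[1] + e0[2] + e0[3]
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"occupancy not conserved at cycle {k}: sum={total}")
        if e0[3] < prev_dead - 1e-12:
            raise ModelError(f"DEAD occupancy decreased at cycle {k}")
        prev_dead = e0[3]

        alive0 = s0 + s1 + s2
        ev_min, ev_mod, ev_fat = q * s_min * alive0, q * s_mod * alive0, q * s_fat * alive0
        events[k] = (ev_min, ev_mod, ev_fat)

        if hcc:
            a0 = 0.5 * (s0 + e0[0])
            a1 = 0.5 * (s1 + e0[1])
            a2 = 0.5 * (s2 + e0[2])
        else:
            a0, a1, a2 = s0, s1, s2
        lyrs[k] = (a0 + a1 + a2) * cl

        # ---- costs ------------------------------------------------------
        if closure:
            stable_cost = (c.monthly_aspirin * 3.0) if k < aspirin_cycles else 0.0
            post_extra = dep_cost
        else:
            stable_cost = c.annual_medical_therapy / 4.0 + med_cost + dis_cost
            post_extra = dep_cost + med_cost
        cycle_cost = (
            a0 * stable_cost
            + a1 * (c.quarterly_post_minor + post_extra)
            + a2 * (c.quarterly_post_moderate_severe + post_extra)
            + ev_min * c.acute_minor
            + (ev_mod + ev_fat) * c.acute_moderate_severe
        )

        # ---- utilities --------------------------------------------------
        if closure:
            u_stable = u.stable_closure_first6mo if k < 2 else u.stable_closure_after6mo
        else:
            u_stable = u.stable_medical
        u_pm, u_pms = u.post_minor, u.post_moderate_severe
        if s.age_utility_decline:
            fac = (1.0 - u.age_decline_per_year) ** (k * cl)
            u_stable, u_pm, u_pms = u_stable * fac, u_pm * fac, u_pms * fac
        if k < af_decr_cycles:
            d = s.closure_first_year_utility_decrement
            u_stable, u_pm, u_pms = u_stable - d, u_pm - d, u_pms - d

        base_utility = a0 * u_stable + a1 * u_pm + a2 * u_pms

        # replace event occupants' trapezoidal value with the event utility
        u_pm_dest = u_pms if s.allow_minor_to_modsev else u_pm
        flows = (
            (q * s_min * s0, u_stable, u_pm),
            (q * s_mod * s0, u_stable, u_pms),
            (q * s_fat * s0, u_stable, 0.0),
            (q * s_min * s1, u_pm, u_pm),
            (q * s_mod * s1, u_pm, u_pm_dest),
            (q * s_fat * s1, u_pm, 0.0),
            (q * (s_min + s_mod) * s2, u_pms, u_pms),
            (q * s_fat * s2, u_pms, 0.0),
        )
        corr = 0.0
        for f, u_src, u_dst in flows:
            if f == 0.0:
                continue
            pair = 0.5 * (u_src + u_dst) if hcc else u_src
            ev_value = (pair - u.event_cycle_utility
                        if s.event_utility_is_decrement
                        else u.event_cycle_utility)
            corr += f * (ev_value - pair)

        df = discount_factor(r, (k + 0.5) * cl)
        cost_d[k] += df * cycle_cost
        cost_u[k] += cycle_cost
        qaly[k] += df * (base_utility + corr) * cl

        # ---- first-event (stroke-free) bookkeeping ----------------------
        cum_first_events += never_stroked * q
        never_stroked *= (1.0 - q) * (1.0 - m)
        if (k + 1) % round(1.0 / cl) == 0:
            stroke_free[round((k + 1) * cl)] = 1.0 - cum_first_events

    return CohortTrace(
        strategy=strategy,
        occupancy=occ,
        cycle_cost=cost_d,
        cycle_cost_undiscounted=cost_u,
        cycle_qaly=qaly,
        cycle_life_years=lyrs,
        events=events,
        stroke_free=stroke_free,
        start_age=s.start_age,
        cycle_length=cl,
        discount_rate=r,
        half_cycle_correction=hcc,
    )


def summarize(trace: CohortTrace) -> StrategyResult:
    """Aggregate a trace into arm-level totals."""
    ev = trace.events.sum(axis=0)
    n_years = trace.stroke_free.size - 1
    return StrategyResult(
        strategy=trace.strategy,
        total_cost=float(trace.cycle_cost.sum()),
        total_cost_undiscounted=float(trace.cycle_cost_undiscounted.sum()),
        total_qaly=float(trace.cycle_qaly.sum()),
        life_years=float(trace.cycle_life_years.sum()),
        strokes_minor=float(ev[0]),
        strokes_moderate_severe=float(ev[1]),
        strokes_fatal=float(ev[2]),
        strokes_total=float(ev.sum()),
        stroke_free_survival={y: float(trace.stroke_free[y]) for y in range(n_years + 1)},
        settings_key=trace.settings_key,
    )


def stroke_free_survival(trace: CohortTrace, year: int) -> float:
    """P(no recurrent stroke by ``year``); deaths without a recurrent
    stroke remain stroke-free (cumulative first-event incidence)."""
    n_years = trace.stroke_free.size - 1
    if not 0 <= year <= n_years:
        raise ValueError(f"year {year} beyond horizon {n_years}")
    return float(trace.stroke_free[year])


def run_strategy(strategy: str, p: ParameterSet, lt: LifeTable) -> StrategyResult:
    return summarize(run_cohort(strategy, p, lt))
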