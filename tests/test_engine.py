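"""Cohort engine: conservation, discounting, accrual oracles, survival."""

import dataclasses
import math

import numpy as np
import pytest

from pfo_cea.engine import (CohortTrace, discount_factor, run_cohort,
                            run_strategy, stroke_free_survival, summarize)
from pfo_cea.errors import ModelError
from pfo_cea.parameters import default_parameters, with_value
from pfo_cea.transitions import build_matrix, rate_to_prob


def _with_settings(p, **kw):
    return dataclasses.replace(p, settings=dataclasses.replace(p.settings, **kw))


def _no_recurrence(p):
    return dataclasses.replace(p, clinical=dataclasses.replace(
        p.clinical, annual_recurrence_rate_medical=0.0,
        annual_recurrence_rate_closure=0.0, procedure_mortality=0.0))


class TestDiscountFactor:
    @pytest.mark.parametrize("rate, t, expected", [
        (0.05, 0.0, 1.0),
        (0.05, 1.0, 0.952381),
        (0.05, 10.0, 0.613913),
        (0.0, 7.0, 1.0),
    ])
    def test_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=5e-7)

    def test_domain(self):
        with pytest.raises(ValueError):
            discount_factor(-0.05, 1.0)


class TestConservationLimits:
    def test_no_events_full_utility_no_discount(self, zero_lifetable):
        p = _no_recurrence(default_parameters())
        p = _with_settings(p, discount_rate=0.0)
        p = with_value(p, "stable_medical", 1.0)
        res = run_strategy("medical", p, zero_lifetable)
        assert res.total_qaly == pytest.approx(30.0, abs=1e-9)
        assert res.life_years == pytest.approx(30.0, abs=1e-9)

    def test_annuity_oracle(self, zero_lifetable):
        """No transitions: QALYs reduce to a discounted quarterly annuity."""
        p = _no_recurrence(default_parameters())
        u, r = 0.83, 0.05
        p = with_value(p, "stable_medical", u)
        res = run_strategy("medical", p, zero_lifetable)
        expected = sum(
            u * 0.25 * (1 + r) ** (-(k + 0.5) * 0.25) for k in range(120)
        )
        assert res.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_occupancy_conserved_and_dead_monotone(self, params, lifetable):
        for strategy in ("medical", "closure"):
            trace = run_cohort(strategy, params, lifetable)
            sums = trace.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert np.all(np.diff(trace.occupancy[:, 3]) >= -1e-12)

    def test_discounted_not_above_undiscounted(self, params, lifetable):
        p0 = _with_settings(params, discount_rate=0.0)
        for strategy in ("medical", "closure"):
            disc = run_strategy(strategy, params, lifetable)
            undisc = run_strategy(strategy, p0, lifetable)
            assert disc.total_cost <= undisc.total_cost + 1e-9
            assert disc.total_qaly <= undisc.total_qaly + 1e-9
            assert disc.total_cost_undiscounted == pytest.approx(
                undisc.total_cost, abs=1e-6)


def scalar_oracle(strategy, p, lt):
    """Naive cycle-by-cycle re-implementation of the accrual rules."""
    s = p.settings
    cl = s.cycle_length
    n = round(s.horizon / cl)
    c, u = p.costs, p.utilities
    closure = strategy == "closure"
    rate = (p.clinical.annual_recurrence_rate_closure if closure
            else p.clinical.annual_recurrence_rate_medical)
    q = 1 - math.exp(-rate * cl)
    smin, smod, sfat = p.clinical.severity_split
    monthly = {"aspirin": c.monthly_aspirin, "clopidogrel": c.monthly_clopidogrel,
               "warfarin": c.monthly_warfarin}[s.regimen]

    occ = [1 - (p.clinical.procedure_mortality if closure else 0.0), 0.0, 0.0]
    occ.append(1 - sum(occ))
    total_cost = (c.closure_total if closure else 0.0)
    total_qaly = -(u.procedure_disutility * cl if closure else 0.0)
    life_years = 0.0
    for k in range(n):
        age = s.start_age + k * cl
        mat = build_matrix(strategy, age, p, lt, k)
        end = [sum(occ[i] * mat[i][j] for i in range(4)) for j in range(4)]
        avg = [(occ[j] + end[j]) / 2 for j in range(4)]
        df = (1 + s.discount_rate) ** (-(k + 0.5) * cl)
        alive = occ[0] + occ[1] + occ[2]
        ev = [q * smin * alive, q * smod * alive, q * sfat * alive]
        life_years += (avg[0] + avg[1] + avg[2]) * cl

        if closure:
            stable_cost = monthly * 3 if k < round(s.closure_antiplatelet_years / cl) else 0.0
            extra = c.quarterly_psych_depression * s.depression_prevalence
        else:
            stable_cost = (c.annual_medical_therapy / 4 + monthly * 3
                           + c.quarterly_psych_distress * s.distress_prevalence)
            extra = (c.quarterly_psych_depression * s.depression_prevalence
                     + monthly * 3)
        cost = (avg[0] * stable_cost
                + avg[1] * (c.quarterly_post_minor + extra)
                + avg[2] * (c.quarterly_post_moderate_severe + extra)
                + ev[0] * c.acute_minor + (ev[1] + ev[2]) * c.acute_moderate_severe)

        u_st = (u.stable_closure_first6mo if k < 2 else u.stable_closure_after6mo) \
            if closure else u.stable_medical
        qaly = avg[0] * u_st + avg[1] * u.post_minor + avg[2] * u.post_moderate_severe
        for frac, usrc, udst in [
            (q * smin * occ[0], u_st, u.post_minor),
            (q * smod * occ[0], u_st, u.post_moderate_severe),
            (q * sfat * occ[0], u_st, 0.0),
            (q * smin * occ[1], u.post_minor, u.post_minor),
            (q * smod * occ[1], u.post_minor, u.post_moderate_severe),
            (q * sfat * occ[1], u.post_minor, 0.0),
            (q * (smin + smod) * occ[2], u.post_moderate_severe, u.post_moderate_severe),
            (q * sfat * occ[2], u.post_moderate_severe, 0.0),
        ]:
            qaly += frac * (u.event_cycle_utility - (usrc + udst) / 2)

        total_cost += df * cost
        total_qaly += df * qaly * cl
        occ = end
    return total_cost, total_qaly, life_years


class TestScalarOracle:
    @pytest.mark.parametrize("strategy", ["medical", "closure"])
    def test_engine_matches_naive_five_cycle_run(self, strategy, params, lifetable):
        p = _with_settings(params, horizon=1.25)
        cost, qaly, ly = scalar_oracle(strategy, p, lifetable)
        res = run_strategy(strategy, p, lifetable)
        assert res.total_cost == pytest.approx(cost, abs=1e-9)
        assert res.total_qaly == pytest.approx(qaly, abs=1e-9)
        assert res.life_years == pytest.approx(ly, abs=1e-9)


class TestHalfCycleCorrection:
    def test_bounded_difference(self, params, lifetable):
        """Trapezoidal vs start-of-cycle accrual differs by less than the
        first-plus-last half-cycle payoffs."""
        on = run_cohort("medical", params, lifetable)
        off = run_cohort("medical", _with_settings(params, half_cycle_correction=False),
                         lifetable)
        for attr in ("cycle_qaly", "cycle_cost", "cycle_life_years"):
            a, b = getattr(on, attr), getattr(off, attr)
            bound = 0.5 * (abs(b[0]) + abs(b[-1])) + 1e-12
            assert abs(a.sum() - b.sum()) < bound


class TestStrokeFreeSurvival:
    def test_recurrence_only_closed_form(self, zero_lifetable, params):
        """Without background mortality the survivor function is the
        exponential of the cycle-compounded recurrence hazard."""
        p = dataclasses.replace(params, clinical=dataclasses.replace(
            params.clinical, procedure_mortality=0.0))
        trace = run_cohort("closure", p, zero_lifetable)
        q = rate_to_prob(0.0058, 0.25)
        assert stroke_free_survival(trace, 10) == pytest.approx(
            (1 - q) ** 40, rel=1e-12)
        assert stroke_free_survival(trace, 10) == pytest.approx(0.9435, abs=5e-4)

    def test_monotone_and_bounds(self, params, lifetable):
        trace = run_cohort("medical", params, lifetable)
        assert stroke_free_survival(trace, 0) == 1.0
        values = [stroke_free_survival(trace, y) for y in range(31)]
        assert all(0 <= v <= 1 for v in values)
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert stroke_free_survival(trace, 20) <= stroke_free_survival(trace, 10)

    def test_year_beyond_horizon(self, params, lifetable):
        trace = run_cohort("medical", params, lifetable)
        with pytest.raises(ValueError):
            stroke_free_survival(trace, 31)


class TestSummarize:
    def test_empty_trace_is_all_zero(self):
        trace = CohortTrace(
            strategy="medical",
            occupancy=np.array([[1.0, 0, 0, 0]]),
            cycle_cost=np.zeros(0), cycle_cost_undiscounted=np.zeros(0),
            cycle_qaly=np.zeros(0), cycle_life_years=np.zeros(0),
            events=np.zeros((0, 3)), stroke_free=np.ones(1),
            start_age=45.0, cycle_length=0.25, discount_rate=0.05,
            half_cycle_correction=True,
        )
        res = summarize(trace)
        assert res.total_cost == res.total_qaly == res.strokes_total == 0.0

    def test_one_cycle_stable_qaly(self, zero_lifetable):
        p = _no_recurrence(default_parameters())
        p = _with_settings(p, horizon=0.25, discount_rate=0.0)
        res = run_strategy("medical", p, zero_lifetable)
        assert res.total_qaly == pytest.approx(0.80 * 0.25, abs=1e-12)

    def test_qaly_bounded_by_life_years(self, base_results):
        for res in base_results.values():
            assert res.total_qaly <= res.life_years
            assert res.total_cost >= 0


class TestGuards:
    def test_life_table_must_cover_span(self, params):
        from pfo_cea.lifetable import LifeTable

        short = LifeTable(np.arange(45, 60), np.full(15, 0.002))
        with pytest.raises(ModelError, match="cover"):
            run_cohort("medical", params, short)

    def test_horizon_must_be_whole_cycles(self, params, lifetable):
        with pytest.raises(ModelError, match="cycles"):
            run_cohort("medical", _with_settings(params, horizon=30.1), lifetable)
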