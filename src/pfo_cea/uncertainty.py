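"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs both arms at a parameter's low and high bounds and
records the swing in net monetary benefit at the configured threshold
(tornado diagram ordering).  Probabilistic analysis samples every
distributed parameter jointly and independently — beta for probabilities
and utilities, gamma for costs, log-normal for relative risks, with
method-of-moments fits treating printed ranges as 95% intervals
(sd = (high - low)/3.92) — and summarises the cloud of incremental
(cost, QALY) pairs as cost-effectiveness-plane quadrant fractions, a
cost-effectiveness acceptability curve, and the per-patient expected value
of perfect information.

To keep the two arms coherent within a draw, the closure-arm recurrence
rate is not sampled independently: a relative risk reduction is drawn from
its log-normal and applied to the sampled medical-arm rate
(rate_closure = rate_medical * (1 - RRR)).  Background mortality is held
fixed across draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import cea
from .engine import run_strategy
from .errors import DistributionError, PfoCeaError
from .lifetable import LifeTable
from .parameters import Family, ParameterSet, parameter_space, with_value

# parameters whose draw is derived from others rather than sampled
_PSA_DERIVED = {"annual_recurrence_rate_closure"}

WTP_GRID_DEFAULT = tuple(
    sorted(set(range(0, 80_001, 1_000)) | {18_827, 37_654})
)


# ---------------------------------------------------------------------------
# distribution fitting


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta fit; requires sd^2 < mean(1-mean)."""
    if not 0.0 < mean < 1.0 or sd <= 0:
        raise DistributionError(f"beta needs mean in (0,1) and sd > 0, got {mean}, {sd}")
    if sd * sd >= mean * (1.0 - mean):
        raise DistributionError(
            f"infeasible beta variance: sd^2={sd * sd:.3g} >= mean(1-mean)={mean * (1 - mean):.3g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma fit, returning (shape, scale)."""
    if mean <= 0 or sd <= 0:
        raise DistributionError(f"gamma needs mean, sd > 0, got {mean}, {sd}")
    return (mean / sd) ** 2, sd * sd / mean


def lognormal_from_ci(low: float, high: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) from a 95% interval on the natural scale."""
    if not 0 < low < high:
        raise DistributionError(f"lognormal needs 0 < low < high, got {low}, {high}")
    return (math.log(low) + math.log(high)) / 2.0, (math.log(high) - math.log(low)) / 3.92


def _range_sd(low: float, high: float) -> float:
    # printed ranges are treated as 95% intervals
    return (high - low) / 3.92


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    nmb_low: float
    nmb_high: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _apply_named(p: ParameterSet, name: str, value: float) -> ParameterSet:
    """Set a parameter, resolving coupled semantics for special names."""
    if name == "rrr_alt":
        p = with_value(p, name, value)
        return with_value(
            p, "annual_recurrence_rate_closure",
            p.clinical.annual_recurrence_rate_medical * (1.0 - value),
        )
    if name == "device_efficacy":
        # sensitivity-only blend: failed closures behave like medical therapy
        p = with_value(p, name, value)
        eff = (value * p.clinical.annual_recurrence_rate_closure
               + (1.0 - value) * p.clinical.annual_recurrence_rate_medical)
        return with_value(p, "annual_recurrence_rate_closure", eff)
    return with_value(p, name, value)


def _compare(p: ParameterSet, lt: LifeTable, wtp: float | None = None) -> cea.CEAResult:
    wtp = p.settings.wtp if wtp is None else wtp
    closure = run_strategy("closure", p, lt)
    medical = run_strategy("medical", p, lt)
    return cea.compare_strategies(closure, medical, wtp)


def one_way(
    param_name: str, p: ParameterSet, lt: LifeTable, wtp: float | None = None
) -> TornadoEntry:
    """NMB at a parameter's low and high bounds, all else at base."""
    bounds = {pv.name: (pv.low, pv.high) for pv in parameter_space(p)}
    if param_name not in bounds:
        raise PfoCeaError(f"parameter {param_name!r} has no one-way range")
    low, high = bounds[param_name]
    try:
        nmb_low = _compare(_apply_named(p, param_name, low), lt, wtp).nmb
        nmb_high = _compare(_apply_named(p, param_name, high), lt, wtp).nmb
    except PfoCeaError as exc:
        raise PfoCeaError(f"one-way analysis failed for {param_name!r}: {exc}") from exc
    return TornadoEntry(param_name, nmb_low, nmb_high)


def tornado(
    p: ParameterSet, lt: LifeTable, params: list[str] | None = None,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, sorted by swing."""
    names = params if params is not None else [pv.name for pv in parameter_space(p)]
    entries = [one_way(name, p, lt, wtp) for name in names]
    return sorted(entries, key=lambda e: e.swing, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _sampler(pv, rng: np.random.Generator):
    if pv.family is Family.BETA:
        a, b = beta_from_moments(pv.base, _range_sd(pv.low, pv.high))
        return lambda: float(rng.beta(a, b))
    if pv.family is Family.GAMMA:
        shape, scale = gamma_from_moments(pv.base, _range_sd(pv.low, pv.high))
        return lambda: float(rng.gamma(shape, scale))
    if pv.family is Family.LOGNORMAL:
        mu, sigma = lognormal_from_ci(pv.low, pv.high)
        return lambda: float(rng.lognormal(mu, sigma))
    return None


def sample_parameter_set(
    p: ParameterSet, rng: np.random.Generator,
    samplers: dict | None = None,
) -> ParameterSet:
    """One joint, independent draw of every distributed parameter."""
    if samplers is None:
        samplers = build_samplers(p, rng)
    draw = p
    for name, f in samplers.items():
        draw = with_value(draw, name, f())
    if "rrr_alt" in samplers:
        # couple the arms: closure rate from the drawn RRR and medical rate
        draw = with_value(
            draw, "annual_recurrence_rate_closure",
            draw.clinical.annual_recurrence_rate_medical * (1.0 - draw.clinical.rrr_alt),
        )
    return draw


def build_samplers(p: ParameterSet, rng: np.random.Generator) -> dict:
    samplers = {}
    for pv in parameter_space(p):
        if pv.family is Family.FIXED or pv.name in _PSA_DERIVED:
            continue
        f = _sampler(pv, rng)
        if f is not None:
            samplers[pv.name] = f
    return samplers


@dataclass
class PSAResult:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    quadrant_fractions: dict[str, float]
    ceac: dict[float, float]
    evpi: float
    wtp: float
    seed: int
    n: int

    @property
    def prob_cost_effective(self) -> float:
        """P(NMB > 0) at the configured threshold."""
        return self.ceac.get(self.wtp, ceac_at(self.delta_cost, self.delta_qaly, self.wtp))


def ceac_at(delta_cost: np.ndarray, delta_qaly: np.ndarray, wtp: float) -> float:
    return float(np.mean(wtp * delta_qaly - delta_cost > 0))


def ceac(
    delta_cost: np.ndarray, delta_qaly: np.ndarray,
    wtp_grid=WTP_GRID_DEFAULT,
) -> dict[float, float]:
    """Acceptability curve: fraction of draws with positive NMB per WTP."""
    delta_cost = np.asarray(delta_cost, dtype=float)
    delta_qaly = np.asarray(delta_qaly, dtype=float)
    if delta_cost.size == 0:
        raise ValueError("empty draw set")
    return {float(w): ceac_at(delta_cost, delta_qaly, w) for w in wtp_grid}


def evpi(delta_cost: np.ndarray, delta_qaly: np.ndarray, wtp: float) -> float:
    """Expected value of perfect information, USD per patient.

    Two-strategy form with the comparator's incremental NMB identically 0:
    E[max(NMB, 0)] - max(E[NMB], 0); non-negative by Jensen's inequality.
    """
    delta_cost = np.asarray(delta_cost, dtype=float)
    delta_qaly = np.asarray(delta_qaly, dtype=float)
    if delta_cost.size == 0:
        raise ValueError("empty draw set")
    nmb = wtp * delta_qaly - delta_cost
    return float(np.mean(np.maximum(nmb, 0.0)) - max(float(np.mean(nmb)), 0.0))


def quadrant_fractions(
    delta_cost: np.ndarray, delta_qaly: np.ndarray, wtp: float
) -> dict[str, float]:
    counts = {d.value: 0 for d in cea.Dominance}
    for dc, dq in zip(delta_cost, delta_qaly):
        counts[cea.classify(float(dc), float(dq), wtp).value] += 1
    n = len(delta_cost)
    return {k: v / n for k, v in counts.items()}


def run_psa(
    p: ParameterSet, lt: LifeTable,
    n: int | None = None, seed: int | None = None,
    wtp_grid=WTP_GRID_DEFAULT,
    samplers: dict | None = None,
) -> PSAResult:
    """Monte Carlo PSA; reproducible for a fixed seed.

    ``samplers`` overrides the per-parameter draw functions (an empty dict
    degenerates every draw to the base case).
    """
    n = p.psa.n_iterations if n is None else n
    seed = p.psa.seed if seed is None else seed
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if samplers is None:
        samplers = build_samplers(p, rng)

    dc = np.empty(n)
    dq = np.empty(n)
    failures = 0
    for i in range(n):
        draw = sample_parameter_set(p, rng, samplers)
        try:
            res = _compare(draw, lt)
        except (PfoCeaError, ValueError):
            # e.g. an RRR draw above 1 implies a negative closure rate;
            # such draws count against the 1% failure budget

            failures += 1
            if failures > max(1, 0.01 * n):
                raise PfoCeaError(
                    f"more than 1% of PSA draws failed ({failures}/{i + 1}); "
                    "distributions are mis-specified"
                )
            dc[i], dq[i] = np.nan, np.nan
            continue
        dc[i], dq[i] = res.delta_cost, res.delta_qaly
    ok = ~np.isnan(dc)
    dc, dq = dc[ok], dq[ok]

    wtp = p.settings.wtp
    return PSAResult(
        delta_cost=dc,
        delta_qaly=dq,
        quadrant_fractions=quadrant_fractions(dc, dq, wtp),
        ceac=ceac(dc, dq, wtp_grid),
        evpi=evpi(dc, dq, wtp),
        wtp=wtp,
        seed=seed,
        n=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# named scenarios


def _scenario_set(name: str, p: ParameterSet) -> ParameterSet:
    s = p.settings
    if name == "no_psych_costs":
        return replace(p, settings=replace(s, psych_costs=False))
    if name == "af_complication":
        return replace(p, settings=replace(
            s, closure_extra_upfront_cost=500.0,
            closure_first_year_utility_decrement=0.05,
        ))
    if name == "table5_rates":
        p = with_value(p, "annual_recurrence_rate_medical", 0.021)
        return with_value(
            p, "annual_recurrence_rate_closure", 0.021 * (1.0 - p.clinical.rrr_alt)
        )
    if name == "cost_plus75":
        return with_value(p, "closure_total", p.costs.closure_total * 1.75)
    if name == "cost_minus75":
        return with_value(p, "closure_total", p.costs.closure_total * 0.25)
    if name == "age_subgroup":
        return replace(p, settings=replace(s, start_age=55.0))
    if name == "horizon_10":
        return replace(p, settings=replace(s, horizon=10.0))
    if name == "horizon_lifetime":
        return replace(p, settings=replace(s, horizon=40.0))
    raise PfoCeaError(
        f"unknown scenario {name!r}; valid: {sorted(SCENARIO_NAMES)}"
    )


SCENARIO_NAMES = frozenset({
    "no_psych_costs", "af_complication", "table5_rates",
    "cost_plus75", "cost_minus75", "age_subgroup",
    "horizon_10", "horizon_lifetime",
})


def scenario(name: str, p: ParameterSet, lt: LifeTable) -> cea.CEAResult:
    """Apply a named modification and return the two-arm comparison."""
    return _compare(_scenario_set(name, p), lt)


def sweep_horizons(
    p: ParameterSet, lt: LifeTable, horizons=(10.0, 20.0, 30.0, 40.0)
) -> dict[float, cea.CEAResult]:
    out = {}
    for h in horizons:
        ph = replace(p, settings=replace(p.settings, horizon=float(h)))
        out[float(h)] = _compare(ph, lt)
    return out
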