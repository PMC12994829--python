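"""Model parameters: defaults, configuration loading, validation.

Every input the cost-effectiveness model uses — clinical event rates, unit
costs, health-state utilities, and run settings — lives here, together with
its deterministic sensitivity range and the distribution family used for
probabilistic sampling.  Defaults describe percutaneous PFO closure versus
medical therapy for secondary prevention after cryptogenic stroke, costed
from the perspective of the Chinese healthcare payer in 2021 US dollars.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

import yaml

from .errors import ConfigError, ValidationError


class Family(str, Enum):
    """Distribution family used when a parameter is sampled in PSA."""

    BETA = "beta"
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    FIXED = "fixed"


@dataclass(frozen=True)
class ParameterValue:
    """One named model input with its base value, range and PSA family."""

    name: str
    base: float
    low: float
    high: float
    family: Family = Family.FIXED
    units: str = ""
    source_tag: str = ""

    def violations(self) -> list[str]:
        out = []
        if not self.low <= self.base <= self.high:
            out.append(
                f"{self.name}: low <= base <= high violated "
                f"({self.low} / {self.base} / {self.high})"
            )
        if self.family is Family.BETA and not (0 <= self.low and self.high <= 1):
            out.append(f"{self.name}: beta family requires bounds within [0, 1]")
        if self.family is Family.GAMMA and self.low < 0:
            out.append(f"{self.name}: gamma family requires low >= 0")
        if self.family is Family.LOGNORMAL and self.low <= 0:
            out.append(f"{self.name}: lognormal family requires low > 0")
        return out


@dataclass(frozen=True)
class ClinicalParameters:
    """Recurrent-stroke epidemiology and procedural risk.

    Annual recurrence rates are per person-year (0.58 vs 1.07 per 100
    patient-years for closure vs medical therapy).  A recurrent event is
    minor (mRS <= 2), moderate-to-severe (mRS 3-5) or fatal, with the split
    taken from Chinese stroke registry data.  Survivors of
    moderate-to-severe stroke carry an elevated background mortality
    (hazard ratio 1.68).
    """

    annual_recurrence_rate_medical: float = 0.0107
    annual_recurrence_rate_closure: float = 0.0058
    severity_minor: float = 0.534
    severity_moderate_severe: float = 0.324
    severity_fatal: float = 0.142
    mortality_hr_moderate_severe: float = 1.68
    procedure_mortality: float = 0.001
    device_efficacy: float = 0.95  # sensitivity-only blending multiplier
    rrr_alt: float = 0.53  # alternative relative-risk-reduction parameterization

    @property
    def severity_split(self) -> tuple[float, float, float]:
        return (self.severity_minor, self.severity_moderate_severe, self.severity_fatal)


@dataclass(frozen=True)
class CostParameters:
    """Unit costs in 2021 USD (Chinese payer perspective)."""

    device: float = 4938.0
    procedure: float = 517.0
    hospitalization: float = 1180.0
    closure_total: float = 6635.0
    acute_minor: float = 1901.0
    acute_moderate_severe: float = 2513.0
    quarterly_post_minor: float = 338.0
    quarterly_post_moderate_severe: float = 514.0
    monthly_aspirin: float = 0.80
    monthly_clopidogrel: float = 8.50
    monthly_warfarin: float = 2.30
    annual_medical_therapy: float = 485.0
    quarterly_psych_depression: float = 125.0
    quarterly_psych_distress: float = 89.0


@dataclass(frozen=True)
class UtilityParameters:
    """EQ-5D style health-state utilities on the 0 (death) - 1 scale."""

    stable_medical: float = 0.80
    stable_closure_first6mo: float = 0.84
    stable_closure_after6mo: float = 0.88
    post_minor: float = 0.76
    post_moderate_severe: float = 0.21
    event_cycle_utility: float = 0.20
    procedure_disutility: float = 0.02
    age_decline_per_year: float = 0.02  # scenario-only
    psych_depression: float = 0.65  # scenario-only
    psych_high_distress: float = 0.72  # scenario-only
    psych_low_distress: float = 0.85  # scenario-only


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings.

    The cohort enters at ``start_age`` and is simulated over ``horizon``
    years in 3-month cycles, with costs and QALYs discounted at
    ``discount_rate`` per year and half-cycle correction on by default.
    ``wtp`` is the willingness-to-pay threshold (three times 2021 Chinese
    per-capita GDP).  Psychological-comorbidity costs are applied at the
    stated prevalences: quarterly depression/anxiety costs to post-stroke
    occupants in both arms, and quarterly high-distress costs to stable
    occupants of the medical arm only (stroke anxiety relieved by closure).
    """

    start_age: float = 45.0
    horizon: float = 30.0
    cycle_length: float = 0.25
    discount_rate: float = 0.05
    wtp: float = 37654.0
    half_cycle_correction: bool = True
    regimen: str = "aspirin"  # antithrombotic in the medical arm
    closure_antiplatelet_years: float = 1.0
    psych_costs: bool = True
    depression_prevalence: float = 0.40
    distress_prevalence: float = 0.40
    age_utility_decline: bool = False
    event_utility_is_decrement: bool = False
    allow_minor_to_modsev: bool = True
    closure_extra_upfront_cost: float = 0.0  # AF-complication scenario hook
    closure_first_year_utility_decrement: float = 0.0


@dataclass(frozen=True)
class PSASettings:
    n_iterations: int = 10_000
    seed: int = 20210521


@dataclass(frozen=True)
class ParameterSet:
    clinical: ClinicalParameters = field(default_factory=ClinicalParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    settings: ModelSettings = field(default_factory=ModelSettings)
    psa: PSASettings = field(default_factory=PSASettings)


_SECTIONS = {
    "clinical": ClinicalParameters,
    "costs": CostParameters,
    "utilities": UtilityParameters,
    "settings": ModelSettings,
    "psa": PSASettings,
}

# Deterministic sensitivity ranges and PSA families.  Ranges are the printed
# 95% intervals where a source interval exists, otherwise +/-25% of the base
# value.  Probabilities and utilities sample beta, costs gamma, relative
# risks log-normal; FIXED entries are varied one-way only (or not at all).
_RANGES: dict[str, tuple[str, float, float, Family]] = {
    "annual_recurrence_rate_medical": ("clinical", 0.008025, 0.013375, Family.BETA),
    "annual_recurrence_rate_closure": ("clinical", 0.0042, 0.0074, Family.BETA),
    "rrr_alt": ("clinical", 0.35, 0.70, Family.LOGNORMAL),
    "mortality_hr_moderate_severe": ("clinical", 1.26, 2.10, Family.LOGNORMAL),
    "procedure_mortality": ("clinical", 0.0, 0.005, Family.BETA),
    "device_efficacy": ("clinical", 0.85, 0.99, Family.FIXED),
    "closure_total": ("costs", 4976.0, 8294.0, Family.GAMMA),
    "acute_minor": ("costs", 1426.0, 2376.0, Family.GAMMA),
    "acute_moderate_severe": ("costs", 1885.0, 3141.0, Family.GAMMA),
    "quarterly_post_minor": ("costs", 254.0, 423.0, Family.GAMMA),
    "quarterly_post_moderate_severe": ("costs", 386.0, 643.0, Family.GAMMA),
    "monthly_aspirin": ("costs", 0.60, 1.00, Family.GAMMA),
    "monthly_clopidogrel": ("costs", 6.38, 10.63, Family.GAMMA),
    "monthly_warfarin": ("costs", 1.73, 2.88, Family.GAMMA),
    "annual_medical_therapy": ("costs", 300.0, 700.0, Family.GAMMA),
    "quarterly_psych_depression": ("costs", 94.0, 156.0, Family.GAMMA),
    "quarterly_psych_distress": ("costs", 67.0, 111.0, Family.GAMMA),
    "stable_medical": ("utilities", 0.70, 0.90, Family.BETA),
    "stable_closure_first6mo": ("utilities", 0.74, 0.94, Family.BETA),
    "stable_closure_after6mo": ("utilities", 0.78, 0.98, Family.BETA),
    "post_minor": ("utilities", 0.66, 0.86, Family.BETA),
    "post_moderate_severe": ("utilities", 0.16, 0.26, Family.BETA),
    "event_cycle_utility": ("utilities", 0.15, 0.25, Family.BETA),
    "procedure_disutility": ("utilities", 0.01, 0.05, Family.BETA),
    "psych_depression": ("utilities", 0.55, 0.75, Family.BETA),
    "psych_high_distress": ("utilities", 0.62, 0.82, Family.BETA),
    "psych_low_distress": ("utilities", 0.75, 0.95, Family.BETA),
    "depression_prevalence": ("settings", 0.30, 0.50, Family.BETA),
    "distress_prevalence": ("settings", 0.30, 0.50, Family.BETA),
    "discount_rate": ("settings", 0.03, 0.07, Family.FIXED),
    "horizon": ("settings", 10.0, 40.0, Family.FIXED),
}


def default_parameters() -> ParameterSet:
    return ParameterSet()


def get_value(p: ParameterSet, name: str) -> float:
    section, *_ = _RANGES[name]
    return getattr(getattr(p, section), name)


def with_value(p: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with the named registry parameter replaced."""
    section, *_ = _RANGES[name]
    new_section = replace(getattr(p, section), **{name: value})
    return replace(p, **{section: new_section})


def parameter_space(p: ParameterSet | None = None) -> Iterator[ParameterValue]:
    """Yield every ranged parameter with base values taken from ``p``."""
    p = p or default_parameters()
    for name, (section, low, high, family) in _RANGES.items():
        yield ParameterValue(
            name=name,
            base=getattr(getattr(p, section), name),
            low=low,
            high=high,
            family=family,
        )


# ---------------------------------------------------------------------------
# validation


def validate_parameters(p: ParameterSet) -> list[str]:
    """Return every invariant violation (empty list means valid)."""
    v: list[str] = []
    c = p.clinical

    def _prob(name: str, x: float) -> None:
        if not 0.0 <= x <= 1.0:
            v.append(f"{name}: value {x} outside [0, 1]")

    for name in ("annual_recurrence_rate_medical", "annual_recurrence_rate_closure"):
        if getattr(c, name) < 0:
            v.append(f"{name}: rate {getattr(c, name)} must be >= 0")
    split_sum = c.severity_minor + c.severity_moderate_severe + c.severity_fatal
    if abs(split_sum - 1.0) > 1e-9:
        v.append(f"severity_split: components sum to {split_sum}, expected 1")
    for name in ("severity_minor", "severity_moderate_severe", "severity_fatal",
                 "procedure_mortality", "device_efficacy", "rrr_alt"):
        _prob(name, getattr(c, name))
    if c.mortality_hr_moderate_severe <= 0:
        v.append("mortality_hr_moderate_severe: hazard ratio must be > 0")

    for f in dataclasses.fields(CostParameters):
        if getattr(p.costs, f.name) < 0:
            v.append(f"{f.name}: cost {getattr(p.costs, f.name)} must be >= 0")
    component_sum = p.costs.device + p.costs.procedure + p.costs.hospitalization
    if abs(component_sum - p.costs.closure_total) > 1.0:
        v.append(
            f"closure_total: {p.costs.closure_total} differs from component "
            f"sum {component_sum} by more than $1"
        )

    for f in dataclasses.fields(UtilityParameters):
        _prob(f.name, getattr(p.utilities, f.name))

    s = p.settings
    if s.horizon <= 0:
        v.append(f"horizon: {s.horizon} must be > 0")
    if not 0.0 <= s.discount_rate < 1.0:
        v.append(f"discount_rate: {s.discount_rate} outside [0, 1)")
    if s.cycle_length != 0.25:
        v.append(f"cycle_length: {s.cycle_length} is fixed at 0.25 years")
    if s.wtp < 0:
        v.append(f"wtp: {s.wtp} must be >= 0")
    if s.regimen not in ("aspirin", "clopidogrel", "warfarin"):
        v.append(f"regimen: {s.regimen!r} not one of aspirin/clopidogrel/warfarin")
    _prob("depression_prevalence", s.depression_prevalence)
    _prob("distress_prevalence", s.distress_prevalence)
    if p.psa.n_iterations < 1:
        v.append(f"n_iterations: {p.psa.n_iterations} must be >= 1")

    for pv in parameter_space(p):
        # base of a ranged parameter may legitimately sit outside its one-way
        # range only if the user overrode the base; flag it.
        v.extend(pv.violations())
    return v


# ---------------------------------------------------------------------------
# configuration I/O


def serialize(p: ParameterSet) -> dict:
    return {
        "clinical": dataclasses.asdict(p.clinical),
        "costs": dataclasses.asdict(p.costs),
        "utilities": dataclasses.asdict(p.utilities),
        "settings": dataclasses.asdict(p.settings),
        "psa": dataclasses.asdict(p.psa),
    }


def save_config(p: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize(p), fh, sort_keys=False)


def load_config(path) -> ParameterSet:
    """Load a YAML/JSON configuration, filling gaps with model defaults.

    Unknown sections or keys are rejected; the returned set is validated
    and a :class:`ValidationError` lists every violated invariant.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:  # pragma: no cover - message formatting
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc

    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")

    kwargs = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ConfigError(
                f"{path}: unknown section {section!r} "
                f"(expected one of {sorted(_SECTIONS)})"
            )
        cls = _SECTIONS[section]
        payload = payload or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown key(s) {sorted(unknown)} in section {section!r}"
            )
        kwargs[section] = cls(**payload)

    p = ParameterSet(**kwargs)
    violations = validate_parameters(p)
    if violations:
        raise ValidationError(violations)
    return p
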