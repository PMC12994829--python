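"""Rate/probability conversions and the 4-state transition matrix.

States: STABLE, POST_MINOR (post-recurrent minor stroke, mRS <= 2),
POST_MODSEV (post-recurrent moderate-to-severe stroke, mRS 3-5), DEAD.
There are no recovery transitions out of the post-stroke states; DEAD is
absorbing.

Within a cycle the recurrent-stroke event is resolved first and background
mortality is applied to the event-free remainder (competing risks combined
multiplicatively; alternative orderings differ at O(q*m), below reporting
precision).  Fatal recurrent events move straight to DEAD via the fatal
share of the severity split, separately from background mortality.
Moderate-to-severe survivors carry background mortality inflated by a
hazard ratio applied in the rate domain.
"""

from __future__ import annotations

import math
from enum import IntEnum

import numpy as np

from .errors import ModelError
from .lifetable import LifeTable
from .parameters import ParameterSet


class HealthState(IntEnum):
    STABLE = 0
    POST_MINOR = 1
    POST_MODSEV = 2
    DEAD = 3


STRATEGIES = ("closure", "medical")


def rate_to_prob(rate: float, cycle_length: float) -> float:
    """Constant-hazard conversion: p = 1 - exp(-rate * cycle_length)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be > 0, got {cycle_length}")
    return 1.0 - math.exp(-rate * cycle_length)


def prob_to_rate(p: float, period: float) -> float:
    """Inverse conversion: rate = -ln(1 - p) / period."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    return -math.log1p(-p) / period


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Multiply the underlying hazard: 1 - (1 - p)**hr."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return 1.0 - (1.0 - p) ** hr


def recurrence_rate(p: ParameterSet, strategy: str) -> float:
    """Annual recurrent-stroke rate for a strategy arm."""
    if strategy == "closure":
        return p.clinical.annual_recurrence_rate_closure
    if strategy == "medical":
        return p.clinical.annual_recurrence_rate_medical
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def build_matrix(
    strategy: str,
    age: float,
    p: ParameterSet,
    lt: LifeTable,
    cycle_index: int = 0,
) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix for one cycle.

    The recurrent hazard continues in the post-stroke states at the same
    strategy-specific rate; a new minor event does not change state (it is
    still counted as an event by the engine), a new moderate-to-severe
    event moves POST_MINOR occupants onward unless the scenario toggle
    disallows it, and the fatal share moves any living state to DEAD.
    """
    cl = p.settings.cycle_length
    q = rate_to_prob(recurrence_rate(p, strategy), cl)
    m = rate_to_prob(lt.annual_mortality(age), cl)
    m_hr = apply_hazard_ratio(m, p.clinical.mortality_hr_moderate_severe)
    s_min, s_mod, s_fat = p.clinical.severity_split

    stable = (
        (1 - q) * (1 - m),
        q * s_min,
        q * s_mod,
        q * s_fat + (1 - q) * m,
    )
    if p.settings.allow_minor_to_modsev:
        minor = (
            0.0,
            q * s_min + (1 - q) * (1 - m),
            q * s_mod,
            q * s_fat + (1 - q) * m,
        )
    else:
        minor = (
            0.0,
            q * (s_min + s_mod) + (1 - q) * (1 - m),
            0.0,
            q * s_fat + (1 - q) * m,
        )
    modsev = (
        0.0,
        0.0,
        q * (s_min + s_mod) + (1 - q) * (1 - m_hr),
        q * s_fat + (1 - q) * m_hr,
    )
    dead = (0.0, 0.0, 0.0, 1.0)

    mat = np.array([stable, minor, modsev, dead])
    if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
        raise ModelError(
            f"transition probability outside [0, 1] at age {age} "
            f"({strategy}): pathological inputs"
        )
    row_sums = mat.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        raise ModelError(f"transition rows do not sum to 1: {row_sums}")
    return mat
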