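import numpy as np
import pytest

from pfo_cea import (default_lifetable, default_parameters, run_strategy)
from pfo_cea.lifetable import LifeTable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    return default_lifetable()


@pytest.fixture(scope="session")
def zero_lifetable():
    """Degenerate no-background-mortality table for closed-form checks."""
    ages = np.arange(30, 111)
    return LifeTable(ages, np.zeros(ages.size))


@pytest.fixture(scope="session")
def base_results(params, lifetable):
    """Base-case arm totals, computed once per session."""
    return {
        strategy: run_strategy(strategy, params, lifetable)
        for strategy in ("medical", "closure")
    }
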