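import dataclasses

import numpy as np
import pytest

from asthmacea.params import LifeTable, load_parameters


@pytest.fixture(scope="session")
def base_params():
    """The shipped base-case parameter set (calibrated life table resolved once)."""
    return load_parameters("base_case.yaml")


@pytest.fixture()
def params(base_params):
    """A mutable copy of the base-case parameters."""
    return base_params.copy()


@pytest.fixture(scope="session")
def true_matrix(base_params):
    """The tabulated A-D matrix, used as ground truth for panel simulation."""
    return base_params.base_transitions.matrix()


def set_value(obj, attr: str, value: float, widen: bool = True):
    """Replace a Quantity's point value (widening the range to keep it bracketed)."""
    q = getattr(obj, attr)
    low = min(q.low, value) if widen else q.low
    high = max(q.high, value) if widen else q.high
    setattr(obj, attr, dataclasses.replace(q, value=value, low=low, high=high))


def constant_life_table(q: float, age_min: int = 50, age_max: int = 105) -> LifeTable:
    return LifeTable({a: q for a in range(age_min, age_max + 1)})
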