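import numpy as np
import pandas as pd
import pytest

from filab.registry import default_registry
from filab.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean cohort (no rule violations, no window violations)."""
    cfg = SimulationConfig(n_patients=400, seed=11)
    return generate_cohort(cfg)


def abnormal_value(spec):
    """A value guaranteed outside the reference interval / in an
    abnormal category for one registry item."""
    if spec.is_numeric:
        if spec.reference_high is not None:
            return spec.reference_high + max(1.0, abs(spec.reference_high)) * 0.5
        return spec.reference_low - max(1.0, abs(spec.reference_low)) * 0.5
    return sorted(spec.abnormal_categories)[0]


def normal_value(spec):
    """A value guaranteed inside the reference interval / in no
    abnormal category."""
    if spec.is_numeric:
        lo = spec.reference_low
        hi = spec.reference_high
        if lo is not None and hi is not None:
            return (lo + hi) / 2
        return (lo + 1.0) if hi is None else (hi - 1.0)
    return "negative"


def records_for_stay(registry, abnormal_items=(), missing_items=(), time_h=2.0):
    """One in-window record per registry item as a long DataFrame."""
    rows = []
    for spec in registry:
        if spec.name in missing_items:
            continue
        value = (abnormal_value(spec) if spec.name in abnormal_items
                 else normal_value(spec))
        t = max(time_h, spec.window_low_h)
        rows.append({"stay_id": 1, "item": spec.name, "charttime_h": t,
                     "value": value})
    return pd.DataFrame(rows, columns=["stay_id", "item", "charttime_h", "value"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
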