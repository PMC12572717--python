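import numpy as np
import pandas as pd
import pytest

from pdcmarkov.model import build_transition_table, fit
from pdcmarkov.synthetic import default_true_model, generate_cohort


@pytest.fixture(scope="session")
def true_model():
    return default_true_model()


@pytest.fixture(scope="session")
def small_cohort(true_model):
    """A 250-patient cohort with claims, shared across the suite."""
    return generate_cohort(250, true_model, seed=7)


@pytest.fixture(scope="session")
def transitions(small_cohort):
    return build_transition_table(small_cohort.windows, small_cohort.baseline)


@pytest.fixture(scope="session")
def fitted(true_model, transitions):
    """The final-model fit on the shared cohort."""
    f = fit(true_model.spec, transitions)
    assert f.converged
    return f


def day_queue_coverage(fill_days, supplies, n_days):
    """Independent day-level oracle: stack supply in a queue, consume one
    unit per day from the first fill onward."""
    covered = np.zeros(n_days, dtype=bool)
    stock = 0.0
    fills = dict()
    for d, s in zip(fill_days, supplies):
        fills[d] = fills.get(d, 0) + s
    start = min(fill_days)
    for day in range(start, n_days):
        stock += fills.get(day, 0)
        if stock >= 1:
            covered[day] = True
            stock -= 1
    return covered


@pytest.fixture(scope="session")
def queue_oracle():
    return day_queue_coverage
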