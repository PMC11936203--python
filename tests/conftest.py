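import numpy as np
import pandas as pd
import pytest

import ancineq.variables as V
from ancineq.survey import CountryMeta, pool_surveys
from ancineq.synthetic import (
    default_spec,
    pooled_weights_of,
    simulate_outcome,
    simulate_women,
)


def cix_double_sum(y, x, w, mu=None):
    """O(n^2) oracle for the concentration index.

    C = sum_ij w_i w_j (y_i - y_j) sgn(x_i - x_j) / (2 mu W^2), with no
    fractional-rank computation; ties contribute zero through the sign.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    W = w.sum()
    mu = (w * y).sum() / W if mu is None else mu
    dy = y[:, None] - y[None, :]
    sx = np.sign(x[:, None] - x[None, :])
    num = (w[:, None] * w[None, :] * dy * sx).sum()
    return num / (2.0 * mu * W * W)


@pytest.fixture(scope="session")
def small_spec():
    return default_spec(seed=7, n_per_country=600)


@pytest.fixture(scope="session")
def small_survey(small_spec):
    return simulate_outcome(simulate_women(small_spec))


@pytest.fixture(scope="session")
def pooled_records(small_spec, small_survey):
    """Pooled DataFrame with de-normalized weights, complete cases."""
    women = small_survey.women.copy()
    women[V.WEIGHT_POOLED] = pooled_weights_of(small_spec, women)
    return women


@pytest.fixture(scope="session")
def pooled_dataset(small_spec, small_survey):
    frames = {
        c.country: small_survey.women[small_survey.women[V.COUNTRY] == c.country]
        .drop(columns=[V.COUNTRY])
        .reset_index(drop=True)
        for c in small_spec.countries
    }
    meta = {
        c.country: CountryMeta(c.country, c.total_population, c.n_women)
        for c in small_spec.countries
    }
    return pool_surveys(frames, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
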