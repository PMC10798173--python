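import numpy as np
import pandas as pd
import pytest

from tempopred import history_stats, observer
from tempopred.sequences import ConditionSpec, build_block


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-subject cohort with default observer parameters, shared across tests."""
    rng = np.random.default_rng(2024)
    params = observer.ObserverParams()
    trials, ratings = observer.simulate_cohort(4, params, rng)
    return trials, ratings


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    trials, _ = small_cohort
    feats = history_stats.cohort_features(trials).dropna(subset=["correct"])
    return feats.assign(global_std=feats["condition_std_ms"])


@pytest.fixture(scope="session")
def random_block():
    rng = np.random.default_rng(77)
    return build_block(ConditionSpec(100.0), rng)


def simulate_logit_data(
    rng, n_subjects=12, n_per_subject=150, beta0=0.5, beta1=-0.3, tau=0.5
):
    """Binomial random-intercept data with known parameters; the predictor is
    standard normal."""
    from scipy.special import expit

    rows = []
    for j in range(n_subjects):
        b = rng.normal(0.0, tau)
        x = rng.normal(size=n_per_subject)
        p = expit(beta0 + beta1 * x + b)
        y = (rng.random(n_per_subject) < p).astype(int)
        rows.append(pd.DataFrame({"subject": f"S{j:02d}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_gamma_log_data(
    rng, n_subjects=12, n_per_subject=120, beta0=6.0, beta1=0.1, tau=0.2, shape=15.0
):
    rows = []
    for j in range(n_subjects):
        b = rng.normal(0.0, tau)
        x = rng.normal(size=n_per_subject)
        mu = np.exp(beta0 + beta1 * x + b)
        y = rng.gamma(shape, mu / shape)
        rows.append(pd.DataFrame({"subject": f"S{j:02d}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_gaussian_data(
    rng, n_subjects=10, n_per_subject=30, beta0=1.0, beta1=0.0, tau=0.5, sigma=1.0,
    x=None,
):
    rows = []
    for j in range(n_subjects):
        b = rng.normal(0.0, tau)
        xj = rng.normal(size=n_per_subject) if x is None else np.asarray(x, dtype=float)
        y = beta0 + beta1 * xj + b + rng.normal(0.0, sigma, size=len(xj))
        rows.append(pd.DataFrame({"subject": f"S{j:02d}", "x": xj, "y": y}))
    return pd.concat(rows, ignore_index=True)
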