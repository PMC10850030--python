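import numpy as np
import pytest

from indoorclim import surrogate, synthetic


@pytest.fixture(scope="session")
def outdoor_year():
    """One simulated year at 3-h resolution (shared across tests)."""
    cfg = synthetic.OutdoorClimateConfig(span_years=1, seed=7)
    return synthetic.generate_outdoor_series(cfg)


@pytest.fixture(scope="session")
def feature_matrix(outdoor_year):
    return surrogate.build_feature_matrix(outdoor_year)


@pytest.fixture(scope="session")
def linear_target(feature_matrix):
    """y = 0.5 ta + 10 + N(0, 0.3^2): a known linear building response."""
    rng = np.random.default_rng(0)
    noise = rng.normal(0.0, 0.3, len(feature_matrix))
    return 0.5 * feature_matrix["ta"].to_numpy() + 10.0 + noise


@pytest.fixture(scope="session")
def linear_split(feature_matrix):
    return surrogate.split_dataset(len(feature_matrix), seed=1)


@pytest.fixture(scope="session")
def linear_model(feature_matrix, linear_target, linear_split):
    """Surrogate trained once on the linear-response target."""
    return surrogate.train_surrogate(
        feature_matrix, linear_target, linear_split, seed=2, target="ti"
    )


@pytest.fixture(scope="session")
def ols_baseline(feature_matrix, linear_target, linear_split):
    """Ordinary-least-squares test MAE on the same features (the oracle)."""
    X = np.column_stack([feature_matrix.to_numpy(), np.ones(len(feature_matrix))])
    y = linear_target
    beta, *_ = np.linalg.lstsq(X[linear_split.train], y[linear_split.train], rcond=None)
    pred = X[linear_split.test] @ beta
    return float(np.mean(np.abs(pred - y[linear_split.test])))
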