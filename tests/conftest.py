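import numpy as np
import pandas as pd
import pytest

from dietrisk.phd_scoring import COMPONENTS, DietaryAssessment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


def make_assessment(pid=1, energy=2500.0, index=0, **overrides):
    """Assessment with every intake at 100 g/day unless overridden."""
    intakes = {c: 100.0 for c in COMPONENTS}
    intakes.update(overrides)
    return DietaryAssessment(pid, intakes, energy, index)


@pytest.fixture
def survival_frame():
    """Small random survival dataset with tied times for engine tests."""
    rng = np.random.default_rng(7)
    n = 200
    X = rng.normal(size=(n, 3))
    eta = X @ np.array([0.5, -0.3, 0.0])
    t = rng.exponential(1.0 / np.exp(eta))
    t = np.ceil(t * 8) / 8  # discretize -> ties
    c = rng.exponential(2.0, size=n)
    df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    df["follow_up_years"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    return df
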