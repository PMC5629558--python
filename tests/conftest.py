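import numpy as np
import pytest

from survstrat import ExpressionMatrix, SurvivalTable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_cohort(seed=0, n=200, hr=3.0, cut_quantile=0.6, censor_hi=6.0,
                baseline=0.3, pro_oncogenic=True):
    """Single-feature cohort with a planted cut-off hazard effect."""
    r = np.random.default_rng(seed)
    x = r.normal(5.0, 1.0, n)
    c = np.quantile(x, cut_quantile)
    high = x > c
    risk = high if pro_oncogenic else ~high
    lam = baseline * np.exp(np.log(hr) * risk)
    T = r.exponential(1.0 / lam)
    C = r.uniform(0.0, censor_hi, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    return x, t, e, c


@pytest.fixture
def small_cohort():
    x, t, e, c = make_cohort(seed=1, n=200)
    return x, t, e, c


@pytest.fixture
def small_surv(small_cohort):
    _, t, e, _ = small_cohort
    ids = [f"P{i:03d}" for i in range(len(t))]
    return SurvivalTable(ids, t, e)


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        ["mir-a", "mir-b"], ["S1", "S2"], np.array([[1.5, 2.25], [3.0, 4.125]])
    )
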