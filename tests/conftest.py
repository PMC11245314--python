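import numpy as np
import pytest

import chordwalk as cw


@pytest.fixture
def unit_square() -> cw.Polytope:
    return cw.hypercube(2)


@pytest.fixture
def triangle() -> cw.Polytope:
    """Right isoceles triangle {x >= 0, y >= 0, x + y <= 1}."""
    return cw.simplex(2)


@pytest.fixture
def unit_interval() -> cw.Polytope:
    return cw.Polytope([[1.0], [-1.0]], [1.0, 0.0])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_square_problem(unit_square) -> cw.Problem:
    return cw.Problem(unit_square, cw.uniform_model())


def ess_standard_error_of_mean(series: np.ndarray) -> float:
    """Autocorrelation-aware standard error of a chain's mean."""
    series = np.asarray(series, dtype=float).reshape(-1)
    ess = float(cw.effective_sample_size(series[None, :, None])[0])
    return series.std(ddof=1) / np.sqrt(ess)


def ess_standard_error_of_variance(series: np.ndarray) -> float:
    """Delta-method standard error of a chain's variance estimate."""
    series = np.asarray(series, dtype=float).reshape(-1)
    ess = float(cw.effective_sample_size(series[None, :, None])[0])
    centered = series - series.mean()
    m2 = np.mean(centered ** 2)
    m4 = np.mean(centered ** 4)
    return np.sqrt(max(m4 - m2 ** 2, 0.0) / ess)
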