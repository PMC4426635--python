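import numpy as np
import pytest

from bdcoal.params import BDParams


@pytest.fixture
def std_params() -> BDParams:
    """Workhorse parameter set: lambda=0.5, mu=0.25, T=10."""
    return BDParams(0.5, 0.25, 10.0)


@pytest.fixture
def yule_params() -> BDParams:
    """Pure-birth (Yule) parameters: mu = 0."""
    return BDParams(0.5, 0.0, 6.0)


def ks_distance(samples: np.ndarray, cdf) -> float:
    """Sup distance between the empirical CDF of ``samples`` and ``cdf``."""
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    theo = np.asarray(cdf(x), float)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - theo)), np.max(np.abs(emp_lo - theo))))
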