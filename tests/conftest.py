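import math

import numpy as np
import pytest

from molcount import BinaryScoreSet, ExperimentCondition


def q_sum_oracle(p: float, f_l: float, n_sat: int) -> float:
    """Brute-force positive-state probability: explicit sum over the
    occupancy distribution with exact binomial coefficients.

    Independent of the closed form used by the implementation.
    """
    total = 0.0
    for k in range(n_sat + 1):
        total += math.comb(n_sat, k) * (1 - f_l) ** k * p**k * (1 - p) ** (n_sat - k)
    return 1.0 - total


def make_score(f_l: float, V: int, V_plus: int, sample_id: str = "s0",
               concentration: float = float("nan")) -> BinaryScoreSet:
    return BinaryScoreSet(
        condition=ExperimentCondition(f_l=f_l, concentration=concentration,
                                      sample_id=sample_id),
        V=V,
        V_plus=V_plus,
    )


def ks_distance(samples: np.ndarray, grid: np.ndarray, density: np.ndarray) -> float:
    """KS distance between an empirical sample and a gridded density."""
    cdf = np.cumsum(density)
    cdf /= cdf[-1]
    x = np.sort(np.asarray(samples).ravel())
    theo = np.interp(x, grid, cdf)
    emp = np.arange(1, x.size + 1) / x.size
    return float(np.max(np.abs(theo - emp)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
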