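import numpy as np
import pytest

from ptimebox import TimeCourseSet


@pytest.fixture
def small_tcs() -> TimeCourseSet:
    """3 courses x 4 time points, one missing value (g2 at t=2)."""
    values = np.array(
        [
            [1.0, 1.2, 0.8, 1.1],
            [2.0, np.nan, 2.5, 2.2],
            [-1.0, -0.5, 0.0, 0.5],
        ]
    )
    return TimeCourseSet(ids=["g1", "g2", "g3"], times=[0.0, 0.5, 2.0, 5.0], values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260904)


def random_tcs(rng: np.random.Generator, n: int, t: int, missing_prob: float = 0.1) -> TimeCourseSet:
    values = rng.normal(0.0, 2.0, size=(n, t))
    if missing_prob > 0:
        mask = rng.random((n, t)) < missing_prob
        full_rows = mask.all(axis=1)
        mask[full_rows, 0] = False
        values[mask] = np.nan
    ids = [f"c{i:03d}" for i in range(n)]
    return TimeCourseSet(ids=ids, times=list(range(1, t + 1)), values=values)
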