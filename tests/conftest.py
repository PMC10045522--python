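import numpy as np
import pytest

from seedvigor import GerminationTimeCourse


@pytest.fixture
def worked_example_tc() -> GerminationTimeCourse:
    """20 seeds, counts (10, 5, 5) over days 1-3: the hand-computable case."""
    return GerminationTimeCourse(
        species="soybean", treatment="CTRL", replicate="1",
        total_seeds=20, times=(1, 2, 3), counts=(10, 5, 5),
    )


@pytest.fixture
def heat_shock_tcs() -> list[GerminationTimeCourse]:
    """Three replicates of 20 seeds with zero germination over 3 days."""
    return [
        GerminationTimeCourse(
            species="soybean", treatment="HS", replicate=str(r),
            total_seeds=20, times=(1, 2, 3), counts=(0, 0, 0),
        )
        for r in (1, 2, 3)
    ]


def random_time_course(rng: np.random.Generator, max_days: int = 6,
                       total_seeds: int = 40) -> GerminationTimeCourse:
    """A random valid time course for property tests."""
    days = int(rng.integers(1, max_days + 1))
    counts = rng.multinomial(int(rng.integers(0, total_seeds + 1)),
                             np.ones(days) / days)
    return GerminationTimeCourse(
        species="x", treatment="T", replicate="1", total_seeds=total_seeds,
        times=tuple(float(d) for d in range(1, days + 1)),
        counts=tuple(int(c) for c in counts),
    )
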