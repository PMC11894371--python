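import numpy as np
import pytest

from stressrep import CurveMatrix, StressCurveDataset, generate, preset


@pytest.fixture
def parallel_curve():
    """Two parallel replicates over two timepoints (no crossings)."""
    return CurveMatrix("p", times=[0.0, 30.0], values=[[4.0, 4.0], [6.0, 6.0]])


@pytest.fixture
def crossing_curve():
    """Same values arranged so the two replicates cross once."""
    return CurveMatrix("x", times=[0.0, 30.0], values=[[4.0, 6.0], [6.0, 4.0]])


@pytest.fixture
def synthetic_style_dataset():
    """11 individuals x 4 replicates x 4 timepoints, complete and positive."""
    return generate(preset("synthetic", seed=11))


@pytest.fixture
def small_dataset():
    """Tiny hand-built dataset: 2 individuals, 2 replicates, 2 timepoints."""
    times = [0.0, 30.0]
    return StressCurveDataset(
        name="tiny",
        curves=(
            CurveMatrix("a", times, [[5.0, 20.0], [6.0, 22.0]]),
            CurveMatrix("b", times, [[4.0, 25.0], [9.0, 12.0]]),
        ),
    )


def random_complete_curve(rng, n_rep=None, n_time=None, individual_id="r"):
    """Random strictly positive complete curve for property tests."""
    n_rep = n_rep or int(rng.integers(2, 6))
    n_time = n_time or int(rng.integers(2, 5))
    values = rng.uniform(0.5, 40.0, size=(n_rep, n_time))
    times = np.cumsum(rng.uniform(1.0, 15.0, size=n_time))
    return CurveMatrix(individual_id, times=times, values=values)
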