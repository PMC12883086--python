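import numpy as np
import pytest

from betamodes import DetectionParams, generate_fixture_dataset

FIXTURE_SEED = 1234


@pytest.fixture(scope="session")
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default synthetic fixture: 50 unimodal + 25 bimodal + 25 trimodal
    probes, 500 samples, fixed master seed."""
    return generate_fixture_dataset(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_dataset):
    return fixture_dataset[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_dataset):
    return fixture_dataset[1]


def brute_force_stationary_points(density: np.ndarray):
    """Independent oracle: collapse runs of equal density values, then
    compare each run with both neighbouring runs.

    A run strictly greater than both neighbours is a maximum (reported
    at the run's first index); a run strictly smaller is a minimum
    (reported at the run's last index, the point where the curve starts
    rising again).  Boundary runs have only one neighbour and are never
    extrema.
    """
    density = np.asarray(density, dtype=float)
    starts = [0]
    for i in range(1, density.size):
        if density[i] != density[starts[-1]]:
            starts.append(i)
    ends = starts[1:] + [density.size]
    values = [density[s] for s in starts]
    maxima, minima = [], []
    for k in range(1, len(values) - 1):
        if values[k] > values[k - 1] and values[k] > values[k + 1]:
            maxima.append(starts[k])
        elif values[k] < values[k - 1] and values[k] < values[k + 1]:
            minima.append(ends[k] - 1)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def random_bump_curve(rng: np.random.Generator, grid_size: int = 512) -> np.ndarray:
    """A random smooth curve: mixture of 1-5 Gaussian bumps on [0, 1].

    Bump widths are kept wide enough that the Gaussian tails never
    underflow to exact zero on the grid, so the curve is strictly
    smooth everywhere (no accidental floating-point plateaus at the
    edges, where the two detectors' boundary conventions differ).
    """
    k = int(rng.integers(1, 6))
    centers = rng.uniform(0.0, 1.0, k)
    widths = rng.uniform(0.05, 0.2, k)
    heights = rng.uniform(0.2, 1.0, k)
    grid = np.linspace(0.0, 1.0, grid_size)
    curve = np.zeros(grid_size)
    for c, w, h in zip(centers, widths, heights):
        curve += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return curve
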