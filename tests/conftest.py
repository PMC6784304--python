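import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from handoverid.datagen import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive enumeration of all monotone warping paths from (0,0) to
    (T_a-1, T_b-1) with unit diagonal/horizontal/vertical steps; independent
    oracle for the DP implementation (tiny inputs only)."""
    na, nb = a.shape[0], b.shape[0]
    cost = lambda i, j: float(np.linalg.norm(a[i] - b[j]))
    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == na - 1 and j == nb - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < na and jj < nb:
                walk(ii, jj, acc + cost(ii, jj))

    walk(0, 0, cost(0, 0))
    return best[0]


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 pairs x 32 trials x 1 replicate, short trajectories; the default
    effect hierarchy (identity >> condition, no trait effect)."""
    cfg = GeneratorConfig(n_pairs=2, replicates=1, t_range=(30, 45), seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_frame(tiny_dataset):
    from handoverid.pipeline import build_frame

    return build_frame(tiny_dataset)


@pytest.fixture(scope="session")
def tiny_distances(tiny_dataset):
    from handoverid.dtw import distance_matrix

    return distance_matrix(tiny_dataset.trajectories)
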