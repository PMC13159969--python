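import numpy as np
import pytest

from meapop.datatypes import IsingParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ising_k3(rng):
    """Moderate random pairwise model on 3 units."""
    h = rng.normal(-1.0, 0.5, 3)
    J = rng.normal(0.0, 0.5, (3, 3))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0.0)
    return IsingParameters(h=h, J=J)


def nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each time in a, distance to the nearest time in sorted b."""
    if b.size == 0:
        return np.full(a.size, np.inf)
    pos = np.searchsorted(b, a)
    left = np.clip(pos - 1, 0, b.size - 1)
    right = np.clip(pos, 0, b.size - 1)
    return np.minimum(np.abs(a - b[left]), np.abs(a - b[right]))


def match_planted_units(catalog, truth, tol_s=1e-3):
    """Greedy matching of sorted units to planted truth; returns per-true-unit
    (recall, precision) using the best-recall sorted unit."""
    out = []
    valid = catalog.valid_units()
    for ts_true in truth.spike_times_s:
        recalls = [np.mean(nearest_distances(ts_true, u.spike_times_s) <= tol_s)
                   for u in valid]
        best = int(np.argmax(recalls))
        u = valid[best]
        precision = np.mean(nearest_distances(u.spike_times_s, ts_true) <= tol_s)
        out.append((float(recalls[best]), float(precision)))
    return out
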