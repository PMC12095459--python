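import numpy as np
import pytest

import polariscape as ps
from polariscape.mollify import MollifiedLandscape, MollifierConfig


@pytest.fixture(scope="session")
def toy3():
    """Mutual-activation pair + repressed reporter; attractors known by hand."""
    return ps.make_toy_network("pair-reporter")


@pytest.fixture(scope="session")
def reference_landscape():
    return ps.make_reference_landscape()


@pytest.fixture(scope="session")
def double_well():
    """Symmetric double well: pass at the midpoint, height a*(D/2)^2 = 0.25."""
    return ps.make_double_well(a=(1.0, 1.0), separation=1.0)


@pytest.fixture(scope="session")
def single_well():
    return ps.Landscape(
        labels=("w",), centers=np.array([[0.0, 0.0]]), steepness=np.array([1.0])
    )


@pytest.fixture(scope="session")
def double_well_mollified(double_well):
    return MollifiedLandscape(double_well, MollifierConfig(radius=0.01))


def random_landscape(rng, n_min=2, n_max=6):
    """Random small landscape with well-separated centers."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        centers = rng.uniform(-3, 3, size=(n, 2))
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.5:
            break
    steep = rng.uniform(0.2, 3.0, size=n)
    return ps.Landscape(
        labels=tuple(f"b{i}" for i in range(n)), centers=centers, steepness=steep
    )
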