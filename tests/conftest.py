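import numpy as np
import pytest

import artiphys as ap


@pytest.fixture(scope="session")
def bank():
    """The standard 362-stimulus descriptor bank."""
    return ap.generate_shape_bank(seed=1)


@pytest.fixture(scope="session")
def full_grid():
    return ap.build_grid()


@pytest.fixture(scope="session")
def full_pred(full_grid, bank):
    """Cached unit-scale predictions for the full 16^4 grid (built once)."""
    return ap.prediction_matrix(full_grid, bank)


@pytest.fixture(scope="session")
def small_grid():
    return ap.build_grid(n_per_axis=4)


@pytest.fixture(scope="session")
def small_pred(small_grid, bank):
    return ap.prediction_matrix(small_grid, bank)


@pytest.fixture(scope="session")
def toy_bank():
    """Ten descriptor-only shapes with random boundary elements."""
    rng = np.random.default_rng(42)
    shapes = []
    for i in range(10):
        els = tuple(
            ap.BoundaryElement(float(c), float(a))
            for c, a in zip(rng.uniform(-1, 1, 6), rng.uniform(0, 360, 6))
        )
        shapes.append(ap.BoundaryShape(f"toy{i}", els))
    return shapes
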