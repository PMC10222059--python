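import numpy as np
import pytest

from popvuln.rasters import ClimateStack, GridGeometry


@pytest.fixture
def geo9():
    """3x3 grid of 10 m cells with origin at (0, 0)."""
    return GridGeometry(x0=0.0, y0=0.0, cell_size=10.0, n_rows=3, n_cols=3)


@pytest.fixture
def small_stack():
    """Deterministic 10x10 two-layer stack with mild correlation."""
    rng = np.random.default_rng(42)
    geo = GridGeometry(x0=0.0, y0=0.0, cell_size=100.0, n_rows=10, n_cols=10)
    a = rng.standard_normal((10, 10))
    b = 0.3 * a + rng.standard_normal((10, 10))
    return ClimateStack({"a": a, "b": b}, geo)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run on the default synthetic conditions (shared)."""
    import warnings

    from popvuln import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(seed=1)
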