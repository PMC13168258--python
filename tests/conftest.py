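import numpy as np
import pytest

import thirty30 as t30


@pytest.fixture(scope="session")
def world():
    """One default synthetic world shared by read-only tests."""
    return t30.generate(t30.WorldConfig(seed=0))


@pytest.fixture(scope="session")
def baseline_net(world):
    return t30.build_baseline(world.pa_records, world.grid, world.land)


@pytest.fixture
def grid4():
    return t30.Grid(4, 4, cell_size_km=5.0)


@pytest.fixture
def grid3():
    return t30.Grid(3, 3, cell_size_km=5.0)


def supersample_coverage(geometry, grid, n=100):
    """Independent supersampling oracle for per-cell coverage fractions:
    the fraction of an n x n lattice of sub-cell sample points falling
    inside the geometry."""
    import shapely

    s = grid.cell_size_km
    frac = np.zeros(grid.shape)
    offs = (np.arange(n) + 0.5) / n * s
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            xs = grid.origin_x_km + c * s + offs
            ys = grid.origin_y_km + r * s + offs
            xx, yy = np.meshgrid(xs, ys)
            pts = shapely.points(xx.ravel(), yy.ravel())
            frac[r, c] = shapely.intersects(geometry, pts).mean()
    return frac
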