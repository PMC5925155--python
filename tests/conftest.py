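import numpy as np
import pytest

import phasemorph as pm


@pytest.fixture(scope="session")
def cell_model():
    """Reference nucleated-cell phantom (6 um body, 2.5 um nucleus at x=3)."""
    return pm.nucleated_cell_model()


@pytest.fixture(scope="session")
def grid():
    """Reference 15 x 15 um^2 / 255 x 255 px raster."""
    return pm.nucleated_cell_grid()


@pytest.fixture(scope="session")
def phase_map(cell_model, grid):
    return pm.render_phase_map(cell_model, grid)


@pytest.fixture(scope="session")
def gx(phase_map):
    return pm.forward_diff_gradient(phase_map, "x")


@pytest.fixture(scope="session")
def center_row_profile(gx, grid):
    return pm.extract_profile(gx, pm.RowLine(grid.nearest_row(0.0)))


def make_profile(samples, padded_tail=False):
    """Wrap raw samples as a LineProfile on a throwaway grid."""
    n = len(samples)
    g = pm.GridSpec(width=float(n), height=2.0, nx=n, ny=2)
    return pm.LineProfile(
        samples=np.asarray(samples, dtype=float),
        pixel_indices=np.arange(n),
        geometry=pm.RowLine(0),
        grid=g,
        step_um=1.0,
        padded_tail=padded_tail,
    )
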