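"""Shared fixtures: small grids and helpers built programmatically."""

import numpy as np
import pytest

from gnptherm.tissue import VoxelGrid


def make_uniform_grid(
    shape=(5, 5, 20),
    spacing=0.5,
    mu_abs=1.0,
    mu_sca=0.0,
    g=0.0,
    k=0.5,
    rho=1000.0,
    cv=3600.0,
) -> VoxelGrid:
    """Homogeneous rectangular grid with no inert voxels (test scaffolding)."""
    nx, ny, nz = shape

    def full(v):
        return np.full(shape, float(v))

    return VoxelGrid(
        spacing=spacing,
        mu_abs=full(mu_abs),
        mu_sca=full(mu_sca),
        g=full(g),
        k=full(k),
        rho=full(rho),
        cv=full(cv),
        region=np.zeros(shape, dtype=np.int32),
        layer_names=["uniform"],
    )


@pytest.fixture
def uniform_grid():
    return make_uniform_grid()


@pytest.fixture(scope="session")
def coarse_domain():
    """1 mm layered skin + tumor domain shared by the slower integration tests."""
    from gnptherm.tissue import build_domain
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_domain(spacing=1.0)
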