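import numpy as np
import pytest

from nichekit import (ClimateStack, GridGeometry, VirtualSpeciesSpec, Window,
                      generate_climate_stack)


@pytest.fixture(scope="session")
def stack64():
    """Six smooth layers on a 64x64 grid; layers 1 and 2 are collinear."""
    return generate_climate_stack(seed=1, nrows=64, ncols=64, n_layers=6,
                                  collinear_groups=[[1, 2]])


@pytest.fixture(scope="session")
def stack_for_species():
    """Larger grid used for virtual-species sampling."""
    return generate_climate_stack(seed=11, nrows=96, ncols=96, n_layers=3)


@pytest.fixture()
def gradient_stack():
    """Two analytic layers: a pure latitudinal and a pure longitudinal gradient."""
    geom = GridGeometry(nrows=20, ncols=30, xll=0.0, yll=0.0, cellsize=0.5)
    lat = np.repeat(geom.lat_centers[:, None], geom.ncols, axis=1)
    lon = np.repeat(geom.lon_centers[None, :], geom.nrows, axis=0)
    return ClimateStack(geom, ["latgrad", "longrad"], np.stack([lat, lon]))


def half_plane_species(n_native=2000, n_introduced=2000, seed=42):
    """Symmetric Gaussian niche; native samples restricted to the left
    half-plane through the niche center, introduced unrestricted."""
    return VirtualSpeciesSpec(
        niche_center=np.array([0.0, 0.0]),
        niche_cov=np.array([[0.25, 0.0], [0.0, 0.25]]),
        native_window=Window(xmax=0.0),
        introduced_window=Window(),
        n_native=n_native,
        n_introduced=n_introduced,
        seed=seed,
    )
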