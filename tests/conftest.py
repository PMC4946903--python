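import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tissuedyn.synthetic import (  # noqa: E402
    DeformationScript,
    apply_deformation_series,
    make_hex_sheet,
)


@pytest.fixture(scope="session")
def hex_sheet():
    """8x8 hexagonal lattice (static reference network)."""
    return make_hex_sheet(8, 8)


@pytest.fixture(scope="session")
def interior_cells(hex_sheet):
    """Cells with no background contact."""
    return [
        c
        for c in hex_sheet.cell_ids
        if 0 not in hex_sheet.neighbors(c, include_background=True)
    ]


@pytest.fixture(scope="session")
def deep_cells(hex_sheet, interior_cells):
    """Interior cells all of whose neighbours are interior too."""
    inter = set(interior_cells)
    return [c for c in interior_cells if hex_sheet.neighbors(c) <= inter]


@pytest.fixture(scope="session")
def shear_movie(hex_sheet):
    return apply_deformation_series(
        hex_sheet, DeformationScript.pure_shear(n_frames=6)
    )


@pytest.fixture(scope="session")
def iso_movie(hex_sheet):
    return apply_deformation_series(
        hex_sheet, DeformationScript.isotropic(n_frames=6)
    )


@pytest.fixture(scope="session")
def static_movie(hex_sheet):
    return apply_deformation_series(hex_sheet, DeformationScript.identity(4))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
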