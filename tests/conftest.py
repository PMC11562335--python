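"""Shared fixtures: small rendered scenes and reference masks."""

import numpy as np
import pytest

from berrymorph import make_grid_spec, rasterize_ellipse_mask, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """A rendered 2x3 grid with 6 markers, plus its spec and ground truth."""
    spec = make_grid_spec(2, 3, seed=11)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def full_scene():
    """A rendered 5x6 grid (the study layout), with shading."""
    spec = make_grid_spec(5, 6, seed=1)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def disk_mask():
    return rasterize_ellipse_mask(100, 100)


@pytest.fixture(scope="session")
def ellipse_mask():
    return rasterize_ellipse_mask(100, 50)


@pytest.fixture()
def square_mask():
    m = np.zeros((120, 120), dtype=bool)
    m[10:110, 10:110] = True
    return m
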