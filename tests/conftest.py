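import numpy as np
import pytest

from memtube.profilequant import estimate_rho0
from memtube.synthgen import (
    DEFAULT_OPTICS,
    NOISELESS_OPTICS,
    MembraneObjectSpec,
    make_flat_film_scene,
    render_scene,
)

FILM_ROI = (10, 5, 118, 80)
FILM_BG_ROI = (10, 95, 118, 126)


def straight_tubule_image(
    diameter_nm, lipid_density=5.0, optics=NOISELESS_OPTICS, seed=0, pixel_size_nm=100.0
):
    """One horizontal tubule in a small frame; returns (image, analysis centerline)."""
    y = 24 * pixel_size_nm
    cl = np.array([[y, 15 * pixel_size_nm], [y, 85 * pixel_size_nm]])
    tub = MembraneObjectSpec(
        kind="tubule", centerline_nm=cl, diameter_nm=diameter_nm, lipid_density=lipid_density
    )
    images, truth = render_scene([tub], optics, (48, 100), pixel_size_nm, seed=seed)
    inner = np.array([[y, 22 * pixel_size_nm], [y, 78 * pixel_size_nm]])
    return images["lipid"], inner


def film_calibration(optics=NOISELESS_OPTICS, seed=0, lipid_density=5.0, pixel_size_nm=100.0):
    film, _ = make_flat_film_scene(
        optics, seed=seed, image_shape=(128, 128), pixel_size_nm=pixel_size_nm,
        lipid_density=lipid_density,
    )
    bg_roi = FILM_BG_ROI if not optics.noiseless or optics.background_level > 0 else None
    return estimate_rho0(film, FILM_ROI, background_roi=bg_roi or FILM_BG_ROI)


@pytest.fixture(scope="session")
def noiseless_calibration():
    return film_calibration(NOISELESS_OPTICS)


@pytest.fixture(scope="session")
def noisy_calibration():
    return film_calibration(DEFAULT_OPTICS, seed=42)
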