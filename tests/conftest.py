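"""Shared fixtures: small, fast phantom cases reused across the suite."""

import numpy as np
import pytest

from petseg import Ellipsoid, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_case():
    """A realistic but small lesion: texture, blur and noise on a 32^3 grid."""
    cfg = PhantomConfig(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        tumors=[Ellipsoid((64.0, 64.0, 64.0), (22.0, 20.0, 24.0), 8.0)],
        texture_amplitude=0.15,
        noise_sd_suv=0.10,
        seed=11,
    )
    return generate_phantom(cfg, lesion_id="T0")


@pytest.fixture(scope="session")
def clean_case():
    """A noiseless, unblurred two-level phantom (background 1, tumor 8)."""
    cfg = PhantomConfig(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        tumors=[Ellipsoid((64.0, 64.0, 64.0), (24.0, 24.0, 24.0), 8.0)],
        texture_amplitude=0.0,
        psf_fwhm_mm=0.0,
        noise_sd_suv=0.0,
        seed=3,
    )
    return generate_phantom(cfg, lesion_id="CLEAN")


@pytest.fixture(scope="session")
def confounder_case():
    """A lesion whose rough mask annexes part of an adjacent hot organ."""
    cfg = PhantomConfig(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        tumors=[Ellipsoid((56.0, 60.0, 60.0), (16.0, 16.0, 16.0), 7.0)],
        confounders=[Ellipsoid((90.0, 60.0, 60.0), (12.0, 12.0, 12.0), 7.7)],
        rough_includes_confounders=True,
        texture_amplitude=0.1,
        noise_sd_suv=0.08,
        seed=21,
    )
    return generate_phantom(cfg, lesion_id="CONF")


def random_mask(rng: np.random.Generator, shape=(6, 6, 6), spacing=(4.0, 4.0, 4.0), p=0.4):
    from petseg import BinaryMask

    return BinaryMask(values=rng.random(shape) < p, spacing=spacing)
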