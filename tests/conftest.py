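import numpy as np
import pytest
from hypothesis import settings

import nucquant as nq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def enrichment_scene_pair():
    """Matched noisy/noise-free scenes with 1.8x Gaussian mark enrichment
    (sigma 200 nm) planted at ~110 transcription sites.

    The two stacks share placement, texture and site streams (same seed);
    only the Poisson detection noise differs, so the noise-free stack is the
    planted signal sampled on the same geometry.
    """

    def params(photon):
        return nq.SceneParams(
            field_shape=(7, 768, 768), voxel_size=(300.0, 85.0, 85.0),
            n_nuclei=110, nucleus_radius=1800.0, nucleus_radius_sd=100.0,
            min_gap=250.0, mark_mode="uniform", spot_fraction=1.0,
            enrichment_amplitude=1.8, enrichment_sigma=200.0,
            spot_intensity_mean=5.0, photon_scale=photon, seed=11,
        )

    noisy, truth = nq.generate_scene(params(500.0))
    clean, _ = nq.generate_scene(params(0.0))
    return noisy, clean, truth


@pytest.fixture(scope="session")
def stage_scene_pair():
    """20-nucleus scenes with identical optics/noise, differing only in mark
    texture: spatially uniform vs a Gaussian random field (correlation
    kernel 300 nm) — the uniform-vs-heterogeneous contrast."""

    def make(mode):
        return nq.generate_scene(nq.SceneParams(
            field_shape=(7, 700, 700), voxel_size=(300.0, 85.0, 85.0),
            n_nuclei=20, nucleus_radius=2500.0, nucleus_radius_sd=150.0,
            mark_mode=mode, grf_kernel_sigma=300.0, grf_contrast=0.25,
            psf_sigma=(250.0, 80.0, 80.0), photon_scale=200.0,
            read_noise_sd=0.02, seed=21,
        ))

    return make("uniform"), make("grf")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
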