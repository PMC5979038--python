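import numpy as np
import pytest

from ftszring import simulate


@pytest.fixture(scope="session")
def snr3_photon_scale() -> float:
    return simulate.photon_scale_for_snr(3.0)


@pytest.fixture()
def noiseless_ring_pair():
    """Noiseless movies at +34 and -34 nm/s with the same geometry."""

    def make(speed: float, **overrides):
        cfg = simulate.RingSimConfig(
            linear_speed_nm_s=speed,
            shot_noise=False,
            read_noise_sd=0.0,
            seed=0,
            **overrides,
        )
        return simulate.simulate_ring_movie(cfg)

    return make


@pytest.fixture()
def gaussian_spot_frame():
    """Factory for frames holding one Gaussian spot on a flat background."""

    def make(x0, y0, amplitude=150.0, sigma=1.3, size=24, background=100.0, noise_sd=0.0, rng=None):
        yy, xx = np.mgrid[0:size, 0:size]
        img = background + amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
        )
        if noise_sd > 0:
            img = img + (rng or np.random.default_rng()).normal(0, noise_sd, img.shape)
        return img

    return make
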