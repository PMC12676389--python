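import numpy as np
import pytest

from smfretglue.config import CorrectionParams, SimulationConfig


@pytest.fixture(scope="session")
def correction_params() -> CorrectionParams:
    return CorrectionParams()


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """One-state, unit-gamma, no-noise, no-bleach generator settings."""
    return SimulationConfig(
        state_means=(0.5,),
        state_occupancies=(1.0,),
        gamma_range=(1.0, 1.0),
        leakage_alpha=0.0,
        shot_noise=False,
        read_noise_sigma=0.0,
        background_level=0.0,
        donor_bleach_lifetime=1e9,
        acceptor_bleach_lifetime=1e9,
        n_frames_donor_exc=100,
    )


def render_spot_image(
    shape: tuple[int, int],
    positions: np.ndarray,
    intensity: float = 1000.0,
    psf_sigma: float = 1.2,
    background: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Test helper: render Gaussian spots on a flat background (independent of
    the package's movie renderer: plain dense evaluation over the full image)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, background, dtype=float)
    for x, y in np.atleast_2d(positions):
        img += (
            intensity
            * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2))
            / (2 * np.pi * psf_sigma**2)
        )
    if noise_sigma > 0:
        img += np.random.default_rng(seed).normal(0, noise_sigma, shape)
    return img
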