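import numpy as np
import pytest

from nsphase import synthetic as syn


@pytest.fixture(scope="session")
def doublet_field_clean():
    """Four symmetric 135-degree doublets, no blur, no noise."""
    rng = np.random.default_rng(3)
    specs = syn.random_droplet_field(
        4, (300, 300), rng, radius_px=30,
        theta_a=np.radians(135), theta_b=np.radians(135), rho_a=0.2, rho_b=0.2,
    )
    img, truth = syn.render_image(specs, (300, 300), blur_sigma_px=0, noise_frac=0, seed=3)
    return img, truth


@pytest.fixture(scope="session")
def doublet_field_noisy():
    """Same geometry with 1 px blur and 5% Gaussian noise."""
    rng = np.random.default_rng(3)
    specs = syn.random_droplet_field(
        4, (300, 300), rng, radius_px=30,
        theta_a=np.radians(135), theta_b=np.radians(135), rho_a=0.2, rho_b=0.2,
    )
    img, truth = syn.render_image(specs, (300, 300), blur_sigma_px=1.0, noise_frac=0.05, seed=3)
    return img, truth
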