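import numpy as np
import pytest

import stainsan as ss


@pytest.fixture(scope="session")
def noiseless_spec():
    """Two-domain spec with zero slide-to-slide spread: truth W per domain is exact."""
    return ss.PhantomSpec(domain_spread=0.0, n_images=4)


@pytest.fixture(scope="session")
def phantom(noiseless_spec):
    """One noiseless domain-0 phantom with its ground truth (image, W, H)."""
    return ss.generate_phantom(noiseless_spec, domain=0, index=0)


@pytest.fixture(scope="session")
def phantom_decomp(phantom):
    image, _, _ = phantom
    return ss.decompose(image)


@pytest.fixture(scope="session")
def small_study():
    """Six-image two-domain study with realistic slide-to-slide spread."""
    spec = ss.PhantomSpec(n_images=6, domain_spread=0.02, rng_seed=11)
    train, test, manifest = ss.generate_two_domain_study(spec)
    return spec, train, test, manifest


@pytest.fixture(scope="session")
def fitted_dist(small_study):
    _, train, _, _ = small_study
    colors = [ss.decompose(img).colors for img in train.images]
    return ss.estimate_distribution(colors)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
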