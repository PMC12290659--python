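import numpy as np
import pytest

from plicl.physics import ParameterMaps
from plicl.synthdata import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Compact four-region stack shared by sampling/feature tests."""
    spec = PhantomSpec(n_sections=6, height=128, width=128)
    return make_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def clean_phantom():
    """Jitter- and noise-free stack with identity transforms."""
    spec = PhantomSpec(
        n_sections=4,
        height=96,
        width=96,
        jitter_rotation_deg=0.0,
        jitter_translation_px=0.0,
        noise_sigma=0.0,
        outlier_prob=0.0,
    )
    return make_phantom(spec, seed=3)


def random_maps(rng: np.random.Generator, shape=(32, 32), pixel_size_um=1.3) -> ParameterMaps:
    """Valid random parameter maps for property tests."""
    return ParameterMaps(
        transmittance=rng.uniform(0.05, 1.0, shape),
        direction=rng.uniform(0.0, np.pi, shape),
        retardation=rng.uniform(0.0, 1.0, shape),
        pixel_size_um=pixel_size_um,
    )
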