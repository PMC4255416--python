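import numpy as np
import pytest

from lesionvol.pipeline import run_phantom_pipeline
from lesionvol.synthetic_data import PhantomSpec, default_intensity_model, default_phantom_spec


@pytest.fixture(scope="session")
def zero_spec():
    return default_phantom_spec(0.0, seed=1, small=True)


@pytest.fixture(scope="session")
def zero_result(zero_spec):
    """Noise-free phantom run through the full imaging pipeline."""
    return run_phantom_pipeline(zero_spec)


@pytest.fixture(scope="session")
def noisy_result():
    """Phantom at noise SD = 20% of the inter-class gap."""
    return run_phantom_pipeline(default_phantom_spec(0.2, seed=7, small=True))


def tiny_phantom_spec(noise_frac=0.0, seed=0, **overrides):
    """Coarse 2.5 mm phantom for simulation-heavy property tests."""
    spec = PhantomSpec(
        grid_shape=(48, 56, 48),
        voxel_size_mm=(2.5, 2.5, 2.5),
        brain_semiaxes_mm=(44.0, 54.0, 40.0),
        ventricle_semiaxes_mm=(7.0, 15.0, 7.0),
        ventricle_offset_mm=(12.0, 3.0, 1.0),
        subdural_csf_thickness_mm=5.0,
        cortical_gm_thickness_mm=7.0,
        pv_lesion_spec=[(1.5, (1.0, 0.3, 0.2))],
        dw_lesion_spec=[(0.8, (26.0, -20.0, 8.0))],
        lacune_spec=[],
        intensity_model=default_intensity_model(noise_frac),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


@pytest.fixture()
def tiny_spec():
    return tiny_phantom_spec()
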