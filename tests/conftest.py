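import numpy as np
import pytest

import rbploc as R


def noise_free(**overrides):
    """Sim-scale params with PSF and noise switched off."""
    kw = dict(psf_sigma=0.0, poisson_scale=0.0, gaussian_sd=0.0)
    kw.update(overrides)
    return R.sim_params(**kw)


@pytest.fixture(scope="session")
def default_field():
    """One rendered sim-scale field with default noise, plus its masks."""
    params = R.sim_params(seed=11)
    truth = R.generate_scene(params)
    stack = R.render_stack(truth)
    image = R.max_project(stack)
    masks = R.segment_field(image)
    return params, truth, stack, image, masks


@pytest.fixture(scope="session")
def clean_field():
    """Noise- and blur-free rendered field, plus its masks."""
    params = noise_free(seed=5)
    truth = R.generate_scene(params)
    stack = R.render_stack(truth)
    image = R.max_project(stack)
    masks = R.segment_field(image)
    return params, truth, stack, image, masks


def make_image(channels: dict, pixel_size=0.3, provenance=None):
    return R.FieldImage(
        channels={k: np.asarray(v, dtype=np.float64) for k, v in channels.items()},
        pixel_size=pixel_size,
        provenance=provenance or {},
    )
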