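import numpy as np
import pytest

from mukcoloc.simulate import SimImagingSpec, generate_cells, render_images


@pytest.fixture(scope="session")
def small_imaging_run():
    """50 noiseless-label cells with rendered Poisson images (session-cached)."""
    spec = SimImagingSpec(n_cells=50, seed=11)
    cells, truth = generate_cells(spec)
    images = render_images(cells, truth, spec)
    return spec, cells, truth, images


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
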