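import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracle

from camvessel.dosimetry import RingGeometry
from camvessel.synthetic import PhantomParams, default_roi, generate_vessel_tree, render_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One small, fast phantom with ground truth (400 px, 20 um/px)."""
    params = PhantomParams(
        image_size=(400, 400),
        microns_per_pixel=20.0,
        ring=RingGeometry(0.5),
        ring_thickness_px=8.0,
        n_trunks=2,
        depth=4,
        noise_sd=2.0,
        rng_seed=11,
    )
    tree = generate_vessel_tree(params)
    image, truth = render_phantom(tree, params)
    return params, tree, image, truth


@pytest.fixture(scope="session")
def default_phantom():
    """Full-scale phantom at the default 10 um/px, 1.5 cm ring = 1500 px."""
    params = PhantomParams(rng_seed=5)
    tree = generate_vessel_tree(params)
    image, truth = render_phantom(tree, params)
    roi_mask = default_roi(params).to_mask(params.image_size)
    return params, tree, image, truth, roi_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
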