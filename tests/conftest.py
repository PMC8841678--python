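import numpy as np
import pytest

import cac


@pytest.fixture(scope="session")
def disk_phantom():
    """Noise-free disk phantom, radius 15 px, 160 HU contrast."""
    spec = cac.PhantomSpec(shape="disk", size_px=64, radius_px=15.0,
                           noise_sigma_hu=0.0, seed=11)
    return cac.render_phantom(spec)


@pytest.fixture(scope="session")
def disk_field(disk_phantom):
    return cac.compute_cost_field(disk_phantom.volume[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cost_field(rng, h, w, weights=(0.43, 0.14, 0.43)):
    """Random feature field for graph-search tests (not image-derived)."""
    return cac.CostField(
        s_zx=(rng.random((h, w)) > 0.5).astype(float),
        s_g=rng.random((h, w)),
        grad_row=rng.normal(size=(h, w)),
        grad_col=rng.normal(size=(h, w)),
        weights=weights,
    )
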