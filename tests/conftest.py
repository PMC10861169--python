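import numpy as np
import pytest

import tracelink as tl


@pytest.fixture
def toy_atlas():
    """Four areas z1, z2, u, v; z1 and z2 injected; two regions."""
    names = ("z1", "z2", "u", "v")
    return tl.AreaAtlas(
        area_names=names,
        region_of={"z1": "occ", "z2": "occ", "u": "par", "v": "par"},
        injected=("z1", "z2"),
    )


@pytest.fixture
def toy_weights(toy_atlas):
    """The worked toy: w(z1,u)=2, w(z2,u)=0, w(z1,v)=4, w(z2,v)=6."""
    w = np.zeros((2, 4))
    w[0, 2] = 2.0  # u -> z1
    w[0, 3] = 4.0  # v -> z1
    w[1, 3] = 6.0  # v -> z2
    return tl.WeightMatrix(w=w, atlas=toy_atlas)


def small_dataset(seed=0, n_areas=12, n_injected=8, lam=0.5, density=0.6, spread=0.0):
    """A fast, fully wired synthetic dataset for unit tests."""
    geom = tl.generate_geometry(n_areas, 2, seed=seed, target_dmax=20.0, n_regions=3)
    n_proj = tl.calibrate_projection_count(geom.dist, lam, density)
    fln = tl.generate_edr_network(
        tl.EDRParams(lam=lam, n_projections=n_proj, dist=geom.dist, seed=seed + 1)
    )
    if spread > 0:
        fln = tl.synthetic_weight_noise(fln, spread, seed=seed + 3)
        sums = fln.sum(axis=1, keepdims=True)
        fln = np.divide(fln, sums, out=np.zeros_like(fln), where=sums > 0)
    return tl.make_partial_dataset(fln, geom.dist, geom.atlas, n_injected, seed=seed + 2)


@pytest.fixture
def small_ds():
    return small_dataset()


@pytest.fixture(scope="session")
def macaque_like():
    return tl.macaque_like_dataset(seed=11)


@pytest.fixture(scope="session")
def mouse_like():
    return tl.mouse_like_dataset(seed=11)
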