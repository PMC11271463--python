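import warnings

import numpy as np
import pytest

import enphylo as ep


@pytest.fixture(scope="session")
def small_fixture():
    """A compact study system: 30x30 grid, 5 layers, 10 species."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ep.make_fixture(nrows=30, ncols=30, n_climate=3, n_lulc=2,
                               n_species=10, seed=3)


@pytest.fixture(scope="session")
def small_std(small_fixture):
    """Background sample + standardized current stack for the small system."""
    bg = ep.sample_background(small_fixture.stack, 250, seed=1)
    std, zcur = ep.standardize(small_fixture.stack, bg)
    return bg, std, zcur


@pytest.fixture(scope="session")
def default_fixture():
    """The default study system: 60x60 grid, 8 layers, 32 species."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ep.make_fixture(seed=5)


@pytest.fixture(scope="session")
def default_std(default_fixture):
    bg = ep.sample_background(default_fixture.stack, 1000, seed=1)
    std, zcur = ep.standardize(default_fixture.stack, bg)
    return bg, std, zcur


@pytest.fixture(scope="session")
def default_donors(default_fixture, default_std):
    """ENFA fits for every species with >= 15 cells (imputation donors)."""
    bg, _, zcur = default_std
    return {
        sp: ep.fit_enfa(zcur, occ.cell_ids, bg.cell_ids)
        for sp, occ in default_fixture.occurrences.items()
        if len(occ.cell_ids) >= 15
    }


@pytest.fixture()
def flat_stack():
    """A fully valid 12x12 stack with 3 independent noise layers."""
    rng = np.random.default_rng(42)
    vals = rng.standard_normal((3, 12, 12))
    return ep.EnvStack(["a", "b", "c"], vals, 1.0, (0.0, 0.0),
                       np.zeros((12, 12), dtype=bool))
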