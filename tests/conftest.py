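import numpy as np
import pytest

from evoreserve import synth
from evoreserve.raster import Grid, LandscapeStack
from evoreserve.trees import UltrametricTree


@pytest.fixture(scope="session")
def toy_tree() -> UltrametricTree:
    """Three tips, cherry at height 1, root at height 2."""
    return UltrametricTree.from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture(scope="session")
def landscape() -> LandscapeStack:
    return synth.gen_landscape(seed=11, nrows=48, ncols=48, n_vars=6, autocorr_range=5.0)


@pytest.fixture(scope="session")
def truth(landscape) -> synth.TruthSet:
    response = synth.logistic_response("lv00", center=0.0, slope=3.0)
    return synth.gen_virtual_species(landscape, response, n_lineages=2, seed=5)


@pytest.fixture()
def small_grid() -> Grid:
    return Grid(nrows=8, ncols=8)


@pytest.fixture()
def uniform_stack() -> LandscapeStack:
    rng = np.random.default_rng(0)
    grid = Grid(16, 16)
    layers = {f"v{i}": rng.standard_normal(grid.shape) for i in range(3)}
    return LandscapeStack(grid, layers)
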