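import numpy as np
import pytest

from foldevo import (
    RunConfig,
    SelectionConfig,
    SelectionMode,
    SurrogateEvaluator,
    run_simulation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateEvaluator()


@pytest.fixture(scope="session")
def strong_run():
    """A small strong-selection run shared by engine/analysis tests."""
    cfg = RunConfig(
        population_size=10,
        founder_length=24,
        max_generations=30,
        seed=11,
        selection=SelectionConfig(mode=SelectionMode.STRONG),
    )
    return run_simulation(cfg)


def make_model(cb, plddt, ptm=0.7, chain=None):
    """Build a StructureModel from explicit CB positions (CA placed alongside)."""
    from foldevo import StructureModel

    cb = np.asarray(cb, dtype=float)
    n = len(cb)
    coords = np.zeros((n, 4, 3))
    coords[:, 3] = cb
    coords[:, 1] = cb + np.array([0.0, 0.0, 1.5])  # CA offset, irrelevant to contacts
    coords[:, 0] = coords[:, 1] + np.array([0.0, 0.7, 0.0])
    coords[:, 2] = coords[:, 1] - np.array([0.0, 0.7, 0.0])
    plddt = np.full(n, plddt) if np.isscalar(plddt) else np.asarray(plddt)
    return StructureModel(
        sequence="A" * n,
        coords=coords,
        plddt=plddt,
        ptm=ptm,
        chain_of_residue=np.array(["A"] * n) if chain is None else np.asarray(chain),
    )
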