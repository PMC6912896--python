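import numpy as np
import pytest

from camipy import (
    AssemblyParams,
    Phylogeny,
    RegionalPool,
    TraitSet,
    assemble_local,
    simulate_regional_pool,
)


@pytest.fixture
def tiny_tree() -> Phylogeny:
    """The worked 3-tip tree ((A:1,B:1):1,C:2) with crown age 2."""
    return Phylogeny(
        parent=np.array([3, 3, 4, 4, -1]),
        blen=np.array([1.0, 1.0, 2.0, 1.0, 0.0]),
        labels=["A", "B", "C"],
    )


@pytest.fixture
def tiny_pool(tiny_tree) -> RegionalPool:
    traits = TraitSet({"A": 0.0, "B": 0.5, "C": 3.0}, "BM", sigma2=1.0)
    return RegionalPool(tiny_tree, traits, {"fixture": "tiny"})


@pytest.fixture
def six_tip_pool() -> RegionalPool:
    """Caterpillar-ish 6-tip ultrametric pool used for exhaustive oracles."""
    # ((((A:1,B:1):1,C:2):1,D:3):1,(E:2,F:2):2);  crown age 4
    parent = np.array([6, 6, 7, 8, 9, 9, 7, 8, 10, 10, -1])
    blen = np.array([1.0, 1.0, 2.0, 3.0, 2.0, 2.0, 1.0, 1.0, 1.0, 2.0, 0.0])
    tree = Phylogeny(parent, blen, ["A", "B", "C", "D", "E", "F"])
    traits = TraitSet(
        {"A": 0.1, "B": 0.3, "C": -1.2, "D": 2.0, "E": 0.7, "F": -0.4},
        "BM",
        sigma2=1.0,
    )
    return RegionalPool(tree, traits, {"fixture": "six"})


@pytest.fixture(scope="session")
def medium_pool() -> RegionalPool:
    """A 60-tip simulated pool shared by statistically flavored tests."""
    return simulate_regional_pool(1.0, 0.2, 60, "BM", 1.0, seed=2024)


@pytest.fixture(scope="session")
def medium_local(medium_pool):
    params = AssemblyParams(model="neutral", n=30)
    return assemble_local(medium_pool, params, seed=7)
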