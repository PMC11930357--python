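import numpy as np
import pytest

from ensaxs.core import Conformer, Ensemble
from ensaxs.synthetic import TopologySpec, make_rigid_domain, sample_conformer


@pytest.fixture(scope="session")
def tiny_topology() -> TopologySpec:
    """A fast 36-residue analogue of the monomer layout for unit tests."""
    return TopologySpec(
        n_res=36,
        rigid_domains=((9, 24),),
        phospho_sites=(4, 5, 6),
        basic_segments=((13, 15), (27, 30)),
        acidic_segments=((33, 35),),
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_topology) -> Ensemble:
    confs = [
        sample_conformer(tiny_topology, kappa=k, seed=s, n_sweeps=3)
        for k, s in [(0.0, 1), (0.0, 2), (0.0, 3), (5.0, 4), (5.0, 5), (5.0, 6)]
    ]
    return Ensemble(confs)


def random_conformer(rng: np.random.Generator, n: int = 12, chains: int = 1) -> Conformer:
    per = n // chains
    coords = rng.normal(scale=8.0, size=(n, 3))
    return Conformer(
        coords=coords,
        residue_ids=np.tile(np.arange(1, per + 1), chains),
        chain_ids=np.repeat([chr(65 + c) for c in range(chains)], per),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def globule() -> Conformer:
    coords = make_rigid_domain(50, seed=42)
    return Conformer(coords, np.arange(1, 51), np.array(["A"] * 50))
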