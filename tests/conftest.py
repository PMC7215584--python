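"""Shared fixtures: tiny hand-built worlds and a seeded synthetic world."""

import numpy as np
import pytest

import autoqsp as aq


@pytest.fixture
def tiny_catalog() -> aq.DrugCatalog:
    return aq.DrugCatalog(
        [
            aq.DrugRecord("d1", "alpha", "activator", fingerprint=np.array([1, 1, 0, 0])),
            aq.DrugRecord("d2", "beta", "inhibitor", fingerprint=np.array([1, 0, 1, 0])),
            aq.DrugRecord("d3", "gamma", "dual", fingerprint=np.array([0, 1, 1, 1])),
        ]
    )


@pytest.fixture
def tiny_targets() -> aq.TargetCatalog:
    return aq.TargetCatalog([aq.TargetRecord(t) for t in ("t1", "t2", "t3")])


@pytest.fixture
def tiny_edges() -> aq.InteractionSet:
    return aq.InteractionSet.from_pairs(
        [("d1", "t1"), ("d1", "t2"), ("d2", "t3"), ("d3", "t1")]
    )


@pytest.fixture(scope="session")
def small_world() -> aq.GroundTruth:
    """200 x 400 world at 1% density with a D=5 latent structure."""
    config = aq.WorldConfig(
        n_drugs=200, n_targets=400, latent_dim=5, density=0.01, n_pathways=50, seed=1
    )
    return aq.generate_world(config)
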