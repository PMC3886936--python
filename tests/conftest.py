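"""Shared fixtures: simulated pan-genomes are generated once per session."""

from __future__ import annotations

import pytest

from panforge import pipeline
from panforge.simulate import SimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A compact six-strain pan-genome used by most integration tests."""
    cfg = SimConfig(
        n_core_families=8,
        n_accessory_families=8,
        n_specific_families=3,
        n_hgt_families=3,
        seed=1,
    )
    return simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def small_hits(small_sim):
    return pipeline.run_homology(small_sim)


@pytest.fixture(scope="session")
def small_clusters(small_sim, small_hits):
    return pipeline.run_clustering(small_sim, small_hits)
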