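"""Shared fixtures: seeded synthetic datasets at two scales."""

import numpy as np
import pandas as pd
import pytest

from polysome.cluster import ProfileClusterer
from polysome.quantify import filter_and_center, vst
from polysome.simulate import (
    make_archetypes,
    replicate_map_for,
    simulate_annotation,
    simulate_counts,
)

SEED = 42


@pytest.fixture(scope="session")
def archetypes8():
    return make_archetypes(8)


@pytest.fixture(scope="session")
def synth(archetypes8):
    """Default-scale synthetic dataset (~2,000 isoforms, 8 classes)."""
    counts, truth = simulate_counts(
        archetypes8, n_genes=700, depth=1e6, dispersion=10.0, seed=SEED
    )
    return counts, truth


@pytest.fixture(scope="session")
def synth_normalized(synth):
    counts, truth = synth
    rmap = replicate_map_for(counts.columns)
    v = vst(counts, replicate_map=rmap)
    rel = filter_and_center(v, rmap)
    return v, rel, truth


@pytest.fixture(scope="session")
def synth_clustering(synth_normalized):
    v, rel, truth = synth_normalized
    est = ProfileClusterer(n_clusters=8).fit(rel)
    return est.result_, rel, truth


@pytest.fixture(scope="session")
def small_annotation():
    """Small annotated dataset for sequence-level tests."""
    arcs = make_archetypes(8)
    counts, truth = simulate_counts(arcs, n_genes=40, depth=2e5, seed=7)
    ann = simulate_annotation(truth, seed=8)
    return counts, truth, ann
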