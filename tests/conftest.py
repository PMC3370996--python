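import sys
from itertools import combinations
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mutexbind import MatchParams, pairwise_match, surface_residues
from mutexbind.motifmatch import cluster_matches
from mutexbind.synthetic import FixtureSpec, default_motif, make_toy_chain, plant_motif

SCAFFOLDS = ("helix", "strand", "coil")


@pytest.fixture(scope="session")
def helix12():
    return make_toy_chain(FixtureSpec(seed=1, n_residues=12, scaffold="helix"))


@pytest.fixture(scope="session")
def strand10():
    return make_toy_chain(FixtureSpec(seed=2, n_residues=10, scaffold="strand"))


def planted_trio(seed: int, noise: float = 0.0, k: int = 4, n_residues: int = 14):
    """Three scaffold-diverse chains sharing one planted surface motif."""
    chains = [
        make_toy_chain(FixtureSpec(seed=seed + i, n_residues=n_residues,
                                   scaffold=SCAFFOLDS[i % 3]),
                       chain_id=chr(ord("A") + i))
        for i in range(3)
    ]
    return plant_motif(chains, default_motif(k), noise_sigma=noise, seed=seed)


def match_subnetwork(chains, params: MatchParams | None = None, min_chains=3):
    params = params or MatchParams()
    surfs = {c.chain_id: surface_residues(c) for c in chains}
    matches = []
    for a, b in combinations(sorted(surfs), 2):
        matches.extend(pairwise_match(surfs[a], surfs[b], params))
    return cluster_matches(matches, min_chains=min_chains,
                           overlap_min=params.min_residues), matches


@pytest.fixture(scope="session")
def planted_clusters():
    planted = planted_trio(seed=11)
    clusters, matches = match_subnetwork(planted.chains)
    return planted, clusters, matches
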