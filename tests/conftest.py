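from __future__ import annotations

import numpy as np
import pytest

import kmernet as kn


@pytest.fixture(scope="session")
def three_clade():
    """Baseline 3-clade fixture: genomes, truth, whole-view tables, edges."""
    genomes, truth = kn.simulate(kn.default_three_clade(seed=1))
    tables = [kn.count_genome(g, "whole", 25, "both") for g in genomes]
    kept, _ = kn.deduplicate(tables)
    edges = kn.pairwise_edges(kept)
    return genomes, truth, kept, edges


@pytest.fixture(scope="session")
def structured_fixture():
    """3 clades with a conserved rRNA-like block and clade-A plasmids."""
    genomes, truth = kn.simulate(kn.structured(seed=1))
    return genomes, truth


@pytest.fixture(scope="session")
def structured_edges(structured_fixture):
    """Edge lists for all four views of the structured fixture."""
    genomes, truth = structured_fixture
    out = {}
    for mode in ("whole", "no_rrna", "rrna_only", "plasmid_only"):
        tables = []
        for g in genomes:
            try:
                tables.append(kn.count_genome(g, mode, 25, "both"))
            except kn.errors.EmptyViewError:
                continue
        kept, _ = kn.deduplicate(tables)
        out[mode] = kn.pairwise_edges(kept)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
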