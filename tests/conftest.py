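from __future__ import annotations

import numpy as np
import pytest

from asmdiff.alignio import GenomePair
from asmdiff.pipeline import identify
from asmdiff.simrearrange import (
    SimConfig,
    random_genome,
    simulate_rearrangements,
    truth_alignments,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def mixed_sim():
    """A 2 x 100 kb genome with a mixed batch of every event kind, its truth
    records, ideal alignments, and the full identification result."""
    genome = random_genome(2, 100_000, 0.4, seed=7)
    cfg = SimConfig(
        n_inversions=3, n_transpositions=5, n_translocations=2,
        n_tandem_dups=2, n_distal_dups=3, n_insertions=5, n_deletions=5,
        inversion_size=(500, 2000), transposition_size=(500, 2000),
        distal_dup_size=(500, 2000),
    )
    mutated, truth = simulate_rearrangements(genome, cfg, seed=11)
    alignments = truth_alignments(truth, genome, mutated)
    genomes = GenomePair.from_sequences(genome, mutated)
    result = identify(alignments, genomes)
    return {
        "genome": genome,
        "mutated": mutated,
        "truth": truth,
        "alignments": alignments,
        "genomes": genomes,
        "result": result,
    }
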