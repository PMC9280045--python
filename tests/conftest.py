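import numpy as np
import pytest

from woxkit import synthetic_data as sim
from woxkit.annotation import MotifDefinition, demo_motif_table
from woxkit.io_formats import GeneModel, SequenceRecord


@pytest.fixture(scope="session")
def demo_motifs():
    return demo_motif_table()


@pytest.fixture(scope="session")
def at_motif():
    """A/T-only, non-palindromic motif whose complement alphabet is {C,G}:
    on a C/G background neither strand can match by chance."""
    return MotifDefinition("WBOX", "AATAAA", "stress")


@pytest.fixture(scope="session")
def annotation_bundle():
    """Synthetic genome + gene models + truth, shared across tests."""
    return sim.simulate_annotation_bundle(6, seed=11)


@pytest.fixture
def toy_genome():
    return {"c": SequenceRecord("c", "ATGCCCTAAG")}


@pytest.fixture
def plus_gene():
    return GeneModel("g", "c", "+", [(1, 3), (7, 9)], [(1, 3, 0), (7, 9, 0)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220630)
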