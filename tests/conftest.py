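import numpy as np
import pytest

from regarch.io import GeneFeature, GenomeSequence, TSSRecord, TranscriptionUnit
from regarch.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic genome shared across tests (read-only)."""
    return simulate_all(SimulationConfig(seed=7, n_tus=40))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_genome():
    """A 1 kb linear genome with two + genes and one - gene."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
    genome = GenomeSequence(id="toy", sequence=seq, topology="linear")
    features = [
        GeneFeature("gA", 100, 250, "+"),
        GeneFeature("gB", 300, 480, "+"),
        GeneFeature("gC", 600, 900, "-"),
    ]
    return genome, features


def make_tu(tu_id, start, end, strand, genes, tss_pos=None):
    tss = TSSRecord(position=tss_pos, strand=strand) if tss_pos is not None else None
    return TranscriptionUnit(tu_id=tu_id, start=start, end=end, strand=strand,
                             gene_ids=list(genes), tss=tss)
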