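import numpy as np
import pytest

from pirnatk import io_formats as io
from pirnatk import synthetic_data as sd


@pytest.fixture(scope="session")
def small_scenario():
    """A compact simulated study shared by downstream tests (one seed)."""
    specs = [
        sd.FamilySpec("FAMA", 900, "LTR", copy_number=8, divergence=0.02,
                      full_length_fraction=0.6),
        sd.FamilySpec("FAMB", 1400, "non-LTR", copy_number=12, divergence=0.05,
                      full_length_fraction=0.4),
        sd.FamilySpec("FAMC", 700, "DNA", copy_number=5, divergence=0.0,
                      full_length_fraction=1.0),
    ]
    clusters = [sd.ClusterSpec("ovary"), sd.ClusterSpec("testis"), sd.ClusterSpec("both")]
    genome, truth = sd.simulate_genome(specs, [120_000, 80_000], seed=42, clusters=clusters)
    return {"specs": specs, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def consensus_records(small_scenario):
    truth = small_scenario["truth"]
    return [io.SequenceRecord(f, s) for f, s in sorted(truth.consensus.items())]


def random_alignment(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random gapped alignment rows over {A,C,G,T,N,-} for pi property tests."""
    alphabet = np.array(list("ACGTN-"))
    probs = [0.22, 0.22, 0.22, 0.22, 0.04, 0.08]
    return ["".join(rng.choice(alphabet, size=length, p=probs)) for _ in range(n)]
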