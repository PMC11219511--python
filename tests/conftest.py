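import numpy as np
import pandas as pd
import pytest

from methylrad.digestion import extract_fragments, scan_motifs
from methylrad.io import Genome, SampleMetadata
from methylrad.simulate import simulate_genome

SMALL_MOTIF_COUNTS = {"CCGG": 8, "CCTGG": 6, "CCTGT": 7, "CCAGG": 5}


@pytest.fixture(scope="session")
def small_genome():
    """A 20-kb synthetic genome with 26 planted motif occurrences."""
    genome, truth = simulate_genome(
        length=20_000, motif_counts=SMALL_MOTIF_COUNTS, seed=11
    )
    return genome, truth


@pytest.fixture(scope="session")
def small_sites(small_genome):
    genome, _ = small_genome
    return scan_motifs(genome)


@pytest.fixture(scope="session")
def small_fragments(small_genome, small_sites):
    genome, _ = small_genome
    return extract_fragments(genome, small_sites, circular=True)


@pytest.fixture
def two_group_metadata():
    """A minimal valid design: 3 lab + 3 field samples per origin."""
    rows = []
    for origin in ("Helgoland", "Spitsbergen"):
        tag = origin[0]
        for i in range(3):
            rows.append({"sample_id": f"F{tag}{i}", "origin": origin,
                         "cultivation": "field", "temperature_C": None})
            rows.append({"sample_id": f"L{tag}{i}", "origin": origin,
                         "cultivation": "lab", "temperature_C": 10})
    return SampleMetadata(pd.DataFrame(rows))


def random_dna(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def random_genome():
    return Genome("rand2k", random_dna(2000, seed=42))
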