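import numpy as np
import pytest

from diagmsat.simulate import freq_table_from_dicts
from diagmsat.synth import PlantedLocusSpec, make_genome_pair

MOTIFS = ["AAT", "ACT", "AGC", "ATC", "AAG", "ACC", "ACTG", "AAGT", "AGAT", "ACAT"]


def planted_specs():
    """25 intact + 3 flank-mutated + 2 duplicated-flank loci (deterministic)."""
    rng = np.random.default_rng(5)
    specs = []
    for i in range(25):
        specs.append(
            PlantedLocusSpec(
                MOTIFS[i % len(MOTIFS)],
                int(rng.integers(4, 16)),
                int(rng.integers(4, 16)),
            )
        )
    for i in range(3):
        specs.append(PlantedLocusSpec(MOTIFS[i], 8, 5, flank_mutations=2))
    for i in range(2):
        specs.append(PlantedLocusSpec(MOTIFS[i + 3], 9, 6, duplicate_flanks=True))
    return specs


@pytest.fixture(scope="session")
def genome_pair():
    return make_genome_pair(planted_specs(), background_length=30_000, seed=11)


@pytest.fixture(scope="session")
def diagnostic_freqs():
    """12 fully diagnostic loci: pool A fixed for allele 1, pool B for 2."""
    fa = freq_table_from_dicts({f"L{i:02d}": {1: 1.0} for i in range(12)}, "A")
    fb = freq_table_from_dicts({f"L{i:02d}": {2: 1.0} for i in range(12)}, "B")
    return fa, fb
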