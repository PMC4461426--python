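"""Simulation of multilocus genotypes for six hybrid genotypic classes.

Given parental allele frequencies for two species (pool A and pool B),
genotypes are drawn per locus under the infinite-population Mendelian
expectations of each class:

* ``pure_A`` / ``pure_B``: both gene copies from the own pool;
* ``F1``: one copy from each pool;
* ``F2``: each copy is an F1 gamete — from pool A with probability 1/2;
* ``BC_A``: one F1 gamete and one copy from pool A (``BC_B`` symmetric).

Loci are independent (no linkage), and F2/backcross gametes are drawn
marginally per gene copy rather than by instantiating explicit F1 parents —
equivalent per locus, which is all the downstream classifier uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .popgen import AlleleFreqTable, GenotypeMatrix, Individual

__all__ = [
    "GENOTYPIC_CLASSES",
    "SimulatedDataset",
    "draw_gene_copy",
    "simulate_genotype",
    "simulate_dataset",
    "freq_table_from_dicts",
]

GENOTYPIC_CLASSES = ("pure_A", "pure_B", "F1", "F2", "BC_A", "BC_B")


def freq_table_from_dicts(
    freqs: Mapping[str, Mapping[int, float]], population: str
) -> AlleleFreqTable:
    """Wrap plain {locus: {allele: freq}} maps as an AlleleFreqTable."""
    return AlleleFreqTable(
        population=population,
        freqs={loc: dict(m) for loc, m in freqs.items()},
        n_genotyped={loc: 0 for loc in freqs},
    )


@dataclass
class SimulatedDataset:
    """Simulated genotypes with their true genotypic classes."""

    genotypes: GenotypeMatrix
    truth: list[str]
    seed: Optional[int]
    freq_a: AlleleFreqTable
    freq_b: AlleleFreqTable


def _pool(freqs: AlleleFreqTable, locus: str) -> tuple[np.ndarray, np.ndarray]:
    m = freqs.freqs[locus]
    if not m:
        raise ValueError(f"empty frequency map at locus {locus!r}")
    alleles = np.array(sorted(m), dtype=np.int64)
    probs = np.array([m[a] for a in alleles], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError(f"non-positive total frequency at locus {locus!r}")
    return alleles, probs / total


def draw_gene_copy(
    freqs: AlleleFreqTable, locus: str, rng: np.random.Generator
) -> int:
    """Sample one gene copy from a pool's allele-frequency distribution."""
    alleles, probs = _pool(freqs, locus)
    return int(rng.choice(alleles, p=probs))


def _gamete_pool(cls: str, copy_index: int, rng: np.random.Generator) -> str:
    """Which pool ('A' or 'B') the given gene copy of class ``cls`` is from."""
    if cls == "pure_A":
        return "A"
    if cls == "pure_B":
        return "B"
    if cls == "F1":
        return "A" if copy_index == 0 else "B"
    if cls == "F2":
        return "A" if rng.random() < 0.5 else "B"
    if cls == "BC_A":
        # copy 0 is the F1 gamete, copy 1 the pure parental copy
        return ("A" if rng.random() < 0.5 else "B") if copy_index == 0 else "A"
    if cls == "BC_B":
        return ("A" if rng.random() < 0.5 else "B") if copy_index == 0 else "B"
    raise ValueError(f"unknown genotypic class {cls!r}")


def simulate_genotype(
    cls: str,
    freq_a: AlleleFreqTable,
    freq_b: AlleleFreqTable,
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    """One multilocus genotype for a genotypic class; loci independent."""
    if cls not in GENOTYPIC_CLASSES:
        raise ValueError(f"unknown genotypic class {cls!r}")
    loci = list(freq_a.freqs)
    if set(loci) != set(freq_b.freqs):
        raise ValueError("parental frequency tables cover different loci")
    geno = {}
    for locus in loci:
        copies = []
        for ci in range(2):
            pool = _gamete_pool(cls, ci, rng)
            table = freq_a if pool == "A" else freq_b
            copies.append(draw_gene_copy(table, locus, rng))
        geno[locus] = (copies[0], copies[1])
    return geno


def simulate_dataset(
    n_per_class: int,
    freq_a: AlleleFreqTable,
    freq_b: AlleleFreqTable,
    seed: Optional[int] = None,
    classes: tuple[str, ...] = GENOTYPIC_CLASSES,
) -> SimulatedDataset:
    """Simulate ``n_per_class`` individuals for each genotypic class.

    Individuals are labelled with their class as the population label, and
    the class sequence is returned as the truth vector. Deterministic under a
    fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    loci = list(freq_a.freqs)
    individuals: list[Individual] = []
    truth: list[str] = []
    rows = []
    for cls in classes:
        for i in range(n_per_class):
            geno = simulate_genotype(cls, freq_a, freq_b, rng)
            individuals.append(Individual(id=f"{cls}_{i:04d}", population=cls))
            truth.append(cls)
            rows.append([geno[locus] for locus in loci])
    calls = np.array(rows, dtype=np.int64)
    return SimulatedDataset(
        genotypes=GenotypeMatrix(individuals=individuals, loci=loci, calls=calls),
        truth=truth,
        seed=seed,
        freq_a=freq_a,
        freq_b=freq_b,
    )
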