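"""Marker characterization statistics for two-species genotype data.

Implements the quantities used to judge how diagnostic a microsatellite panel
is: per-population allele frequencies, observed and expected (Nei's 1 - sum
p^2, no small-sample correction) heterozygosities, shared and private allele
counts, Weir & Cockerham's (1984) theta estimator of F_ST, the exact
conditional Hardy-Weinberg test (full enumeration or Monte-Carlo gene-copy
shuffling), and Bonferroni significance thresholds.

Genotypes are diploid, alleles are positive integer codes (fragment sizes),
0 encodes a missing call; missing data are handled by per-locus complete-case
exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Individual",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "allele_frequencies",
    "heterozygosities",
    "shared_private_alleles",
    "shared_allele_frequency_mass",
    "wc_fst",
    "hwe_exact_test",
    "bonferroni_threshold",
]

MISSING = 0


@dataclass(frozen=True)
class Individual:
    id: str
    population: str


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2); allele codes are positive
    integers and 0 marks a missing gene copy (both copies of a missing call
    are 0).
    """

    individuals: list[Individual]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative integers")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        mask = np.array([ind.population == population for ind in self.individuals])
        if not mask.any():
            raise KeyError(f"no individuals in population {population!r}")
        return mask

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        inds = [ind for ind, m in zip(self.individuals, mask) if m]
        return GenotypeMatrix(inds, list(self.loci), self.calls[mask])


@dataclass
class AlleleFreqTable:
    """Per-locus allele->frequency maps for one population sample."""

    population: str
    freqs: dict[str, dict[int, float]]
    n_genotyped: dict[str, int] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


def _pop_calls(genotypes: GenotypeMatrix, population: str, locus: str) -> np.ndarray:
    """Complete-case genotype rows (n, 2) for one population at one locus."""
    mask = genotypes.population_mask(population)
    j = genotypes.locus_index(locus)
    calls = genotypes.calls[mask, j, :]
    ok = (calls != MISSING).all(axis=1)
    return calls[ok]


def allele_frequencies(genotypes: GenotypeMatrix, population: str) -> AlleleFreqTable:
    """Sample allele frequencies per locus for one population.

    Frequency = allele count / (2 x genotyped individuals at that locus).
    A locus with no genotyped individual gets an empty map.
    """
    freqs: dict[str, dict[int, float]] = {}
    n_genotyped: dict[str, int] = {}
    for locus in genotypes.loci:
        calls = _pop_calls(genotypes, population, locus)
        n = calls.shape[0]
        n_genotyped[locus] = n
        if n == 0:
            freqs[locus] = {}
            continue
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        freqs[locus] = {int(a): c / (2 * n) for a, c in zip(alleles, counts)}
    return AlleleFreqTable(population=population, freqs=freqs, n_genotyped=n_genotyped)


def heterozygosities(
    genotypes: GenotypeMatrix, population: str, locus: str
) -> tuple[float, float]:
    """Observed and expected heterozygosity at one locus.

    Ho is the heterozygote fraction among genotyped individuals; He is Nei's
    1 - sum p_i^2 without small-sample correction.
    """
    calls = _pop_calls(genotypes, population, locus)
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"no genotyped individuals at {locus!r} in {population!r}")
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    _, counts = np.unique(calls.ravel(), return_counts=True)
    p = counts / (2 * n)
    he = float(1.0 - (p**2).sum())
    return ho, he


def shared_private_alleles(
    freq_a: AlleleFreqTable, freq_b: AlleleFreqTable, locus: str
) -> tuple[int, int, int, float]:
    """Shared and private allele counts and the shared proportion at a locus.

    shared_proportion = |A intersect B| / |A union B| over the two
    populations' observed allele sets.
    """
    if locus not in freq_a.freqs or locus not in freq_b.freqs:
        raise KeyError(f"locus {locus!r} absent from a frequency table")
    a = set(freq_a.freqs[locus])
    b = set(freq_b.freqs[locus])
    shared = len(a & b)
    total = len(a | b)
    if total == 0:
        raise ValueError(f"locus {locus!r} has no observed alleles")
    return shared, len(a - b), len(b - a), shared / total


def shared_allele_frequency_mass(
    freq_a: AlleleFreqTable, freq_b: AlleleFreqTable, locus: str
) -> float:
    """Mean across the two populations of the frequency mass on shared alleles.

    A frequency-weighted companion to :func:`shared_private_alleles`: alleles
    present in both samples contribute their total frequency in each
    population, and the two totals are averaged.
    """
    shared_set = set(freq_a.freqs[locus]) & set(freq_b.freqs[locus])
    mass_a = sum(freq_a.freqs[locus][a] for a in shared_set)
    mass_b = sum(freq_b.freqs[locus][a] for a in shared_set)
    return (mass_a + mass_b) / 2.0


def _wc_components(
    calls1: np.ndarray, calls2: np.ndarray
) -> Optional[tuple[float, float, float]]:
    """Weir-Cockerham (1984) variance components (a, b, c) summed over
    alleles, for two population samples at one locus.

    Returns None when the locus is monomorphic across both samples or a
    sample has fewer than 2 genotyped individuals.
    """
    n1, n2 = calls1.shape[0], calls2.shape[0]
    if n1 < 2 or n2 < 2:
        return None
    alleles = np.unique(np.concatenate([calls1.ravel(), calls2.ravel()]))
    if alleles.size < 2:
        return None
    r = 2
    n = np.array([n1, n2], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p = np.array(
            [
                (calls1 == allele).sum() / (2 * n1),
                (calls2 == allele).sum() / (2 * n2),
            ]
        )
        h = np.array(
            [
                ((calls1 == allele).sum(axis=1) == 1).mean(),
                ((calls2 == allele).sum(axis=1) == 1).mean(),
            ]
        )
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(
    genotypes: GenotypeMatrix, pop1: str, pop2: str
) -> tuple[dict[str, float], float]:
    """Weir & Cockerham's theta per locus and over all loci for two samples.

    The multilocus estimate is the ratio of summed variance components
    (sum a / sum(a+b+c)), not the mean of per-locus thetas. Loci monomorphic
    across both samples are undefined (NaN per locus, excluded from sums).
    Negative estimates are retained.
    """
    per_locus: dict[str, float] = {}
    a_tot = abc_tot = 0.0
    for locus in genotypes.loci:
        calls1 = _pop_calls(genotypes, pop1, locus)
        calls2 = _pop_calls(genotypes, pop2, locus)
        comps = _wc_components(calls1, calls2)
        if comps is None:
            per_locus[locus] = float("nan")
            continue
        a, b, c = comps
        denom = a + b + c
        per_locus[locus] = a / denom if denom != 0 else float("nan")
        if denom != 0:
            a_tot += a
            abc_tot += denom
    multilocus = a_tot / abc_tot if abc_tot != 0 else float("nan")
    return per_locus, multilocus


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def _genotype_counts(calls: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for a, b in calls:
        key = (int(min(a, b)), int(max(a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _log_array_prob(
    geno_counts: Mapping[tuple[int, int], int], allele_counts: Mapping[int, int]
) -> float:
    """Log conditional probability of a genotype array given allele counts.

    P = n! 2^h prod_i c_i! / ((2n)! prod_{i<=j} n_ij!) with h the number of
    heterozygous individuals (Levene's conditional distribution).
    """
    n = sum(geno_counts.values())
    h = sum(v for (a, b), v in geno_counts.items() if a != b)
    logp = gammaln(n + 1) + h * math.log(2.0) - gammaln(2 * n + 1)
    for c in allele_counts.values():
        logp += gammaln(c + 1)
    for v in geno_counts.values():
        logp -= gammaln(v + 1)
    return float(logp)


def _enumerate_arrays(allele_counts: dict[int, int], max_configs: int):
    """Yield all genotype arrays consistent with the given allele counts.

    Arrays are dicts {(a,b): count} over ordered allele pairs a<=b. Raises
    OverflowError when the enumeration visits more than ``max_configs``
    recursion nodes, which bounds both the number of arrays yielded and the
    total work.
    """
    alleles = sorted(allele_counts)
    pairs = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    total_copies = sum(allele_counts.values())
    if total_copies % 2 != 0:
        raise ValueError("odd total number of gene copies")
    produced = 0

    def rec(idx: int, remaining: dict[int, int], current: dict):
        nonlocal produced
        produced += 1
        if produced > max_configs:
            raise OverflowError("enumeration too large")
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield dict(current)
            return
        a, b = pairs[idx]
        if a == b:
            cap = remaining[a] // 2
        else:
            cap = min(remaining[a], remaining[b])
        for k in range(cap + 1):
            if a == b:
                remaining[a] -= 2 * k
            else:
                remaining[a] -= k
                remaining[b] -= k
            if k:
                current[(a, b)] = k
            yield from rec(idx + 1, remaining, current)
            if k:
                del current[(a, b)]
            if a == b:
                remaining[a] += 2 * k
            else:
                remaining[a] += k
                remaining[b] += k

    yield from rec(0, dict(allele_counts), {})


def hwe_exact_test(
    genotype_counts: Mapping[tuple[int, int], int],
    method: str = "auto",
    reps: int = 100_000,
    seed: Optional[int] = None,
    max_enumeration: int = 1_000_000,
) -> float:
    """Exact conditional test of Hardy-Weinberg proportions at one locus.

    The p-value is the total conditional probability (given the allele
    counts) of genotype arrays no more probable than the observed one, ties
    included. ``method`` is ``"enumeration"``, ``"monte_carlo"``, or
    ``"auto"`` (enumeration when the array space is small enough, otherwise
    Monte-Carlo shuffling of gene copies with ``reps`` replicates).
    A monomorphic locus returns p = 1.
    """
    geno = {(min(a, b), max(a, b)): int(v) for (a, b), v in genotype_counts.items() if v}
    if not geno:
        raise ValueError("no genotypes supplied")
    allele_counts: dict[int, int] = {}
    for (a, b), v in geno.items():
        allele_counts[a] = allele_counts.get(a, 0) + v * (1 if a != b else 2)
        if a != b:
            allele_counts[b] = allele_counts.get(b, 0) + v
    if len(allele_counts) < 2:
        return 1.0

    log_obs = _log_array_prob(geno, allele_counts)
    tol = 1e-9

    if method not in ("auto", "enumeration", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "enumeration"):
        try:
            p = 0.0
            for array in _enumerate_arrays(allele_counts, max_enumeration):
                lp = _log_array_prob(array, allele_counts)
                if lp <= log_obs + tol:
                    p += math.exp(lp)
            return min(p, 1.0)
        except OverflowError:
            if method == "enumeration":
                raise
            # fall through to Monte-Carlo

    if reps < 1000:
        import warnings

        warnings.warn("fewer than 1000 Monte-Carlo replicates", stacklevel=2)
    rng = np.random.default_rng(seed)
    copies = np.concatenate(
        [np.full(c, allele, dtype=np.int64) for allele, c in allele_counts.items()]
    )
    hits = 0
    for _ in range(reps):
        rng.shuffle(copies)
        pairs = copies.reshape(-1, 2)
        sim = _genotype_counts(pairs)
        if _log_array_prob(sim, allele_counts) <= log_obs + tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def genotype_counts_at(
    genotypes: GenotypeMatrix, population: str, locus: str
) -> dict[tuple[int, int], int]:
    """Observed genotype counts for one population at one locus."""
    return _genotype_counts(_pop_calls(genotypes, population, locus))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
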