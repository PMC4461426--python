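"""Bayesian assignment of individuals to six hybrid genotypic classes.

Each genotypic class is characterized by the expected fractions of loci
whose two gene copies descend from (A,A), (A,B) and (B,B) ancestry — the
Mendelian genotype-frequency class table:

=========  =====  =====  =====
class      (A,A)  (A,B)  (B,B)
=========  =====  =====  =====
pure_A       1      0      0
pure_B       0      0      1
F1           0      1      0
F2          1/4    1/2    1/4
BC_A        1/2    1/2     0
BC_B         0     1/2    1/2
=========  =====  =====  =====

Two estimators are provided. ``classify_plugin`` treats the parental allele
frequencies as known and computes each individual's posterior directly from
the product over loci of class likelihoods. ``classify_mcmc`` is a Gibbs
sampler over the full hierarchical model — class indicators, mixing
proportions, per-locus ancestry categories, and Dirichlet-distributed pool
allele frequencies — in which designated reference individuals have their
class fixed and inform the pool frequencies (the known-individual
convention of reference-based hybrid assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .popgen import MISSING, AlleleFreqTable, GenotypeMatrix, Individual
from .simulate import GENOTYPIC_CLASSES, SimulatedDataset, simulate_dataset

__all__ = [
    "CLASS_PROB_TABLE",
    "PosteriorMatrix",
    "ConfusionSummary",
    "genotype_class_likelihood",
    "classify_plugin",
    "classify_mcmc",
    "power_assessment",
]

# Genotype-frequency class table: expected fractions of loci with (A,A),
# (A,B), (B,B) gene-copy ancestry for each genotypic class.
CLASS_PROB_TABLE: dict[str, tuple[float, float, float]] = {
    "pure_A": (1.0, 0.0, 0.0),
    "pure_B": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_A": (0.5, 0.5, 0.0),
    "BC_B": (0.0, 0.5, 0.5),
}

_PHI = np.array([CLASS_PROB_TABLE[c] for c in GENOTYPIC_CLASSES])


@dataclass
class PosteriorMatrix:
    """Per-individual posterior probabilities over the six classes."""

    ids: list[str]
    classes: tuple[str, ...]
    probs: np.ndarray  # (n, 6), rows sum to 1
    mode: str  # "plugin" | "mcmc"
    flagged: list[str] = field(default_factory=list)
    sweeps: Optional[int] = None
    burnin: Optional[int] = None
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.ids, columns=list(self.classes))

    def assigned_class(self) -> list[Optional[str]]:
        """Argmax class per individual; ``None`` on a tie."""
        out: list[Optional[str]] = []
        for row in self.probs:
            top = row.max()
            winners = np.flatnonzero(row >= top - 1e-12)
            out.append(self.classes[winners[0]] if winners.size == 1 else None)
        return out


@dataclass
class ConfusionSummary:
    """Class-level power summary: mean posteriors and argmax accuracies."""

    mean_posterior: pd.DataFrame  # true class x assigned class
    accuracy: pd.Series  # per true class, fraction with argmax == truth
    overall_accuracy: float
    n_per_class: int


def _freqs_at(freqs, locus: str) -> Mapping[int, float]:
    if isinstance(freqs, AlleleFreqTable):
        return freqs.freqs[locus]
    return freqs[locus]


def genotype_class_likelihood(
    genotype: tuple[int, int],
    cls: str,
    freq_a: Mapping[int, float],
    freq_b: Mapping[int, float],
) -> float:
    """P(genotype | class) at one locus given parental allele frequencies.

    Sums over the three ancestry categories weighted by the class table,
    with Hardy-Weinberg genotype probabilities within (A,A) and (B,B) and
    the cross term for (A,B).
    """
    for m in (freq_a, freq_b):
        vals = list(m.values())
        if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-6:
            raise ValueError("allele frequencies must be non-negative and sum to 1")
    if cls not in CLASS_PROB_TABLE:
        raise ValueError(f"unknown genotypic class {cls!r}")
    i, j = genotype
    pai, paj = freq_a.get(i, 0.0), freq_a.get(j, 0.0)
    pbi, pbj = freq_b.get(i, 0.0), freq_b.get(j, 0.0)
    if i == j:
        p_aa = pai * pai
        p_bb = pbi * pbi
        p_ab = pai * pbi
    else:
        p_aa = 2 * pai * paj
        p_bb = 2 * pbi * pbj
        p_ab = pai * pbj + paj * pbi
    phi_aa, phi_ab, phi_bb = CLASS_PROB_TABLE[cls]
    return phi_aa * p_aa + phi_ab * p_ab + phi_bb * p_bb


def classify_plugin(
    genotypes: GenotypeMatrix,
    freq_a: AlleleFreqTable,
    freq_b: AlleleFreqTable,
    prior: Optional[Sequence[float]] = None,
) -> PosteriorMatrix:
    """Posterior class probabilities with parental frequencies plugged in.

    Per individual the posterior is proportional to prior x product over
    loci of the class likelihood; missing calls are skipped. An individual
    whose genotype has zero likelihood under every class (e.g. an allele
    absent from both pools) gets a uniform posterior and is flagged.
    """
    if prior is None:
        prior = np.full(6, 1.0 / 6.0)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (6,) or (prior < 0).any():
        raise ValueError("prior must be 6 non-negative weights")

    n = len(genotypes.individuals)
    with np.errstate(divide="ignore"):
        logpost = np.tile(np.log(prior), (n, 1))
    flagged: list[str] = []
    for idx, ind in enumerate(genotypes.individuals):
        any_locus = False
        for j, locus in enumerate(genotypes.loci):
            a, b = genotypes.calls[idx, j]
            if a == MISSING or b == MISSING:
                continue
            any_locus = True
            fa = _freqs_at(freq_a, locus)
            fb = _freqs_at(freq_b, locus)
            liks = np.array(
                [
                    genotype_class_likelihood((int(a), int(b)), cls, fa, fb)
                    for cls in GENOTYPIC_CLASSES
                ]
            )
            with np.errstate(divide="ignore"):
                logpost[idx] += np.log(liks)
        row = logpost[idx]
        if not np.isfinite(row).any():
            logpost[idx] = 0.0
            flagged.append(ind.id)
        if not any_locus:
            flagged.append(ind.id)
    logpost -= logpost.max(axis=1, keepdims=True)
    probs = np.exp(logpost)
    probs /= probs.sum(axis=1, keepdims=True)
    return PosteriorMatrix(
        ids=[ind.id for ind in genotypes.individuals],
        classes=GENOTYPIC_CLASSES,
        probs=probs,
        mode="plugin",
        flagged=sorted(set(flagged)),
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _encode(genotypes: GenotypeMatrix):
    """Integer-encode alleles per locus for vectorized sampling."""
    n, L = len(genotypes.individuals), len(genotypes.loci)
    allele_maps: list[dict[int, int]] = []
    K = 0
    for j in range(L):
        col = genotypes.calls[:, j, :].ravel()
        alleles = sorted(int(a) for a in np.unique(col) if a != MISSING)
        allele_maps.append({a: i for i, a in enumerate(alleles)})
        K = max(K, len(alleles))
    K = max(K, 1)
    a1 = np.zeros((n, L), dtype=np.int64)
    a2 = np.zeros((n, L), dtype=np.int64)
    miss = np.zeros((n, L), dtype=bool)
    for j in range(L):
        amap = allele_maps[j]
        col = genotypes.calls[:, j, :]
        miss[:, j] = (col == MISSING).any(axis=1)
        for i in range(n):
            if not miss[i, j]:
                a1[i, j] = amap[int(col[i, 0])]
                a2[i, j] = amap[int(col[i, 1])]
    valid = np.zeros((L, K), dtype=bool)
    for j in range(L):
        valid[j, : len(allele_maps[j])] = True
    return a1, a2, miss, valid, allele_maps


def classify_mcmc(
    genotypes: GenotypeMatrix,
    reference: Optional[Mapping[str, str]] = None,
    sweeps: int = 20_000,
    burnin: int = 20_000,
    seed: Optional[int] = None,
    freq_prior: float = 1.0,
) -> PosteriorMatrix:
    """Gibbs-sampler posterior over the six genotypic classes.

    ``reference`` maps individual ids to known classes; those individuals'
    class indicators stay fixed while their gene copies still inform the
    pool allele frequencies. Each sweep resamples (i) the class indicator of
    every non-reference individual from its conditional posterior, (ii) the
    six mixing proportions from their Dirichlet conditional, and (iii) both
    pools' per-locus allele frequencies from Dirichlet conditionals given
    the current ancestry-category allocation of every gene copy. Posteriors
    are indicator averages over the retained sweeps; reference individuals
    are reported with probability 1 on their declared class. Uniform
    Dirichlet priors (``freq_prior`` pseudo-counts per observed allele)
    give prior support to alleles absent from the reference pools.
    """
    if sweeps < 1 or burnin < 0:
        raise ValueError("sweeps must be >= 1 and burnin >= 0")
    rng = np.random.default_rng(seed)
    n, L = len(genotypes.individuals), len(genotypes.loci)
    if n == 0:
        raise ValueError("no individuals to classify")
    a1, a2, miss, valid, _ = _encode(genotypes)
    K = valid.shape[1]

    cls_index = {c: i for i, c in enumerate(GENOTYPIC_CLASSES)}
    ref = np.full(n, -1, dtype=np.int64)
    if reference:
        by_id = {ind.id: i for i, ind in enumerate(genotypes.individuals)}
        for ind_id, cls in reference.items():
            if ind_id not in by_id:
                raise KeyError(f"reference individual {ind_id!r} not in data")
            ref[by_id[ind_id]] = cls_index[cls]
    is_ref = ref >= 0
    free = ~is_ref

    if not valid.any() or (valid.sum(axis=1) < 2).all():
        # no polymorphic locus: the likelihood cannot separate classes
        import warnings

        warnings.warn("no polymorphic loci; returning uniform posteriors")
        probs = np.full((n, 6), 1.0 / 6.0)
        probs[is_ref] = np.eye(6)[ref[is_ref]]
        return PosteriorMatrix(
            ids=[i.id for i in genotypes.individuals],
            classes=GENOTYPIC_CLASSES,
            probs=probs,
            mode="mcmc",
            sweeps=sweeps,
            burnin=burnin,
            seed=seed,
        )

    rows = np.arange(L)[None, :]
    het = (a1 != a2) & ~miss
    obs = ~miss
    # initial state
    theta_a = np.where(valid, 1.0, 0.0)
    theta_a /= theta_a.sum(axis=1, keepdims=True)
    theta_b = theta_a.copy()
    pi = np.full(6, 1.0 / 6.0)
    z = rng.integers(0, 6, size=n)
    z[is_ref] = ref[is_ref]

    accum = np.zeros((n, 6))
    total = burnin + sweeps

    for sweep in range(total):
        tA1 = theta_a[rows, a1]
        tA2 = theta_a[rows, a2]
        tB1 = theta_b[rows, a1]
        tB2 = theta_b[rows, a2]
        mult = np.where(het, 2.0, 1.0)
        g_aa = tA1 * tA2 * mult
        g_bb = tB1 * tB2 * mult
        g_ab = np.where(het, tA1 * tB2 + tA2 * tB1, tA1 * tB1)
        G = np.stack([g_aa, g_ab, g_bb], axis=-1)  # (n, L, 3)
        G[miss] = 1.0

        # class indicators
        cls_lik = np.einsum("nlw,zw->nlz", G, _PHI)
        cls_lik = np.clip(cls_lik, 1e-300, None)
        logpost = np.log(cls_lik).sum(axis=1) + np.log(pi)
        gumbel = rng.gumbel(size=(n, 6))
        z_new = np.argmax(logpost + gumbel, axis=1)
        z = np.where(is_ref, ref, z_new)

        # per-locus ancestry categories
        pw = _PHI[z][:, None, :] * G
        pw_sum = pw.sum(axis=-1, keepdims=True)
        pw = pw / pw_sum
        u = rng.random((n, L, 1))
        w = (u > np.cumsum(pw, axis=-1)).sum(axis=-1)  # 0=AA, 1=AB, 2=BB

        # orientation of the heterozygous (A,B) category
        denom = tA1 * tB2 + tA2 * tB1
        p_first_from_a = np.where(denom > 0, tA1 * tB2 / np.where(denom > 0, denom, 1.0), 0.5)
        first_from_a = rng.random((n, L)) < p_first_from_a

        copy1_a = (w == 0) | ((w == 1) & (het & first_from_a | ~het))
        copy2_a = (w == 0) | ((w == 1) & het & ~first_from_a)
        # for homozygous (A,B) loci one copy goes to each pool (copy1->A)

        locus_idx = np.broadcast_to(np.arange(L), (n, L))
        flat = lambda arr, sel: (locus_idx[sel] * K + arr[sel])  # noqa: E731
        counts_a = np.bincount(
            np.concatenate([flat(a1, obs & copy1_a), flat(a2, obs & copy2_a)]),
            minlength=L * K,
        ).reshape(L, K)
        counts_b = np.bincount(
            np.concatenate([flat(a1, obs & ~copy1_a), flat(a2, obs & ~copy2_a)]),
            minlength=L * K,
        ).reshape(L, K)

        # pool allele frequencies
        g1 = rng.standard_gamma(freq_prior + counts_a) * valid
        theta_a = g1 / g1.sum(axis=1, keepdims=True)
        g2 = rng.standard_gamma(freq_prior + counts_b) * valid
        theta_b = g2 / g2.sum(axis=1, keepdims=True)

        # mixing proportions from the free individuals
        if free.any():
            pi = rng.dirichlet(1.0 + np.bincount(z[free], minlength=6))
        else:
            pi = rng.dirichlet(np.ones(6))

        if sweep >= burnin:
            accum[np.arange(n), z] += 1.0

    probs = accum / sweeps
    probs[is_ref] = np.eye(6)[ref[is_ref]]
    return PosteriorMatrix(
        ids=[i.id for i in genotypes.individuals],
        classes=GENOTYPIC_CLASSES,
        probs=probs,
        mode="mcmc",
        sweeps=sweeps,
        burnin=burnin,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Power assessment
# ---------------------------------------------------------------------------


def _merge(ref_gm: GenotypeMatrix, sim_gm: GenotypeMatrix) -> GenotypeMatrix:
    if ref_gm.loci != sim_gm.loci:
        raise ValueError("loci mismatch between reference and simulated data")
    return GenotypeMatrix(
        individuals=ref_gm.individuals + sim_gm.individuals,
        loci=list(ref_gm.loci),
        calls=np.concatenate([ref_gm.calls, sim_gm.calls], axis=0),
    )


def summarize_assignments(
    posterior: PosteriorMatrix, truth: Mapping[str, str], n_per_class: int
) -> ConfusionSummary:
    """Confusion summary over the individuals present in ``truth``.

    Mean posterior probability by (true class, assigned class) and per-class
    argmax accuracy; posterior ties count as misassignment.
    """
    frame = posterior.to_frame()
    assigned = dict(zip(posterior.ids, posterior.assigned_class()))
    present = set(truth.values())
    classes = [c for c in GENOTYPIC_CLASSES if c in present]
    mean_rows = {}
    acc = {}
    correct_total = 0
    n_total = 0
    for cls in classes:
        ids = [i for i, t in truth.items() if t == cls]
        sub = frame.loc[ids]
        mean_rows[cls] = sub.mean(axis=0)
        hits = sum(1 for i in ids if assigned[i] == cls)
        acc[cls] = hits / len(ids)
        correct_total += hits
        n_total += len(ids)
    return ConfusionSummary(
        mean_posterior=pd.DataFrame(mean_rows).T.loc[classes, classes],
        accuracy=pd.Series(acc).loc[classes],
        overall_accuracy=correct_total / n_total,
        n_per_class=n_per_class,
    )


def power_assessment(
    freq_a: AlleleFreqTable,
    freq_b: AlleleFreqTable,
    n_per_class: int = 100,
    n_ref_per_pool: int = 36,
    sweeps: int = 20_000,
    burnin: int = 20_000,
    seed: Optional[int] = None,
    mode: str = "mcmc",
) -> ConfusionSummary:
    """Simulate six genotypic classes and measure assignment power.

    Simulates ``n_per_class`` individuals per class from the parental
    frequencies, adds ``n_ref_per_pool`` simulated pure individuals of each
    species as known reference individuals (mcmc mode), classifies, and
    tabulates mean posteriors by true class and argmax accuracy over the
    non-reference individuals.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    sim_seed, ref_seed, mcmc_seed = (int(s) for s in rng.integers(2**31 - 1, size=3))
    sim = simulate_dataset(n_per_class, freq_a, freq_b, seed=sim_seed)
    truth = {ind.id: cls for ind, cls in zip(sim.genotypes.individuals, sim.truth)}

    if mode == "plugin":
        posterior = classify_plugin(sim.genotypes, freq_a, freq_b)
    elif mode == "mcmc":
        refs = simulate_dataset(
            n_ref_per_pool, freq_a, freq_b, seed=ref_seed, classes=("pure_A", "pure_B")
        )
        ref_gm = GenotypeMatrix(
            individuals=[
                Individual(id=f"ref_{ind.id}", population=ind.population)
                for ind in refs.genotypes.individuals
            ],
            loci=list(refs.genotypes.loci),
            calls=refs.genotypes.calls,
        )
        combined = _merge(ref_gm, sim.genotypes)
        reference = {
            ind.id: ind.population for ind in ref_gm.individuals
        }
        posterior = classify_mcmc(
            combined,
            reference=reference,
            sweeps=sweeps,
            burnin=burnin,
            seed=mcmc_seed,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return summarize_assignments(posterior, truth, n_per_class)
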