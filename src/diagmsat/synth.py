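"""Synthetic data generators with known truth tables.

Three generators make every pipeline stage testable without external data:

* :func:`make_genome_pair` builds two small assemblies carrying orthologous
  microsatellites with known repeat counts between identical, unique 20-bp
  flanks (optionally with mutated or duplicated flanks), so the scanner and
  the flank matcher can be checked against a planted truth table;
* :func:`make_genotype_dataset` draws two-population diploid genotype data
  with a controllable shared-allele proportion, spanning the range from
  fixed differences to identical allele pools;
* :func:`sparrow_panel` returns a deterministic synthetic reconstruction of
  the allele frequencies of the published 12-locus Saltmarsh/Nelson's
  sparrow diagnostic panel, constrained by its reported per-locus summary
  statistics (allele counts, private-allele counts, most-common-allele
  frequencies in both species, and the frequency-weighted shared-allele
  proportion). The full per-allele frequency appendix is not redistributed
  with this package, so the reconstruction is a stand-in with the same
  summary characteristics, not the original data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .popgen import AlleleFreqTable, GenotypeMatrix, Individual
from .scan import Contig, canonical_motif, find_repeats, is_primitive, revcomp

__all__ = [
    "PlantedLocusSpec",
    "GenomePair",
    "make_genome_pair",
    "DivergenceSpec",
    "make_genotype_dataset",
    "sparrow_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _repeat_spans(seq: str, min_repeats: int) -> list[tuple[int, int]]:
    contig = Contig("tmp", seq)
    return [(L.start, L.end) for L in find_repeats(contig, (3, 4), min_repeats, 0)]


def _clean_seq(rng: np.random.Generator, length: int, min_repeats: int) -> str:
    """Random sequence free of 3/4-mer tandem runs of >= min_repeats copies."""
    seq = list(_random_seq(rng, length))
    for _ in range(100):
        spans = _repeat_spans("".join(seq), min_repeats)
        if not spans:
            return "".join(seq)
        for s, e in spans:
            seq[s:e] = list(_random_seq(rng, e - s))
    raise RuntimeError("could not generate repeat-free background")


@dataclass(frozen=True)
class PlantedLocusSpec:
    """One orthologous repeat locus to plant in both genomes."""

    motif: str
    n_repeats_a: int
    n_repeats_b: int
    flank_mutations: int = 0
    duplicate_flanks: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) not in (3, 4) or not is_primitive(self.motif):
            raise ValueError(f"motif must be a primitive 3/4-mer: {self.motif!r}")
        if self.n_repeats_a < 1 or self.n_repeats_b < 1:
            raise ValueError("repeat counts must be >= 1")
        if self.flank_mutations < 0:
            raise ValueError("flank_mutations must be >= 0")

    @property
    def expected_status(self) -> str:
        if self.duplicate_flanks:
            return "ambiguous"
        if self.flank_mutations > 0:
            return "flank_missing"
        return "matched"


@dataclass
class GenomePair:
    assembly_a: list[Contig]
    assembly_b: list[Contig]
    truth: pd.DataFrame


def _make_flank(
    rng: np.random.Generator,
    length: int,
    motif: str,
    side: str,
    used: set[str],
    min_repeats: int,
) -> str:
    """A unique random flank that cannot extend the planted repeat tract."""
    for _ in range(1000):
        f = _random_seq(rng, length)
        if side == "five" and f[-1] == motif[-1]:
            continue
        if side == "three" and f[0] == motif[0]:
            continue
        if _repeat_spans(f, min_repeats):
            continue
        if f in used or revcomp(f) in used:
            continue
        used.add(f)
        used.add(revcomp(f))
        return f
    raise RuntimeError("could not generate a suitable flank")


def _mutate_flank(
    rng: np.random.Generator, flank: str, n_mut: int, used: set[str]
) -> str:
    """Introduce n_mut substitutions, never touching the last position."""
    for _ in range(1000):
        chars = list(flank)
        positions = rng.choice(len(flank) - 1, size=min(n_mut, len(flank) - 1), replace=False)
        for p in positions:
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[rng.integers(0, 3)]
        f = "".join(chars)
        if f != flank and f not in used and revcomp(f) not in used:
            used.add(f)
            used.add(revcomp(f))
            return f
    raise RuntimeError("could not mutate flank to a unique sequence")


def make_genome_pair(
    specs: Sequence[PlantedLocusSpec],
    background_length: int = 20_000,
    seed: Optional[int] = 0,
    flank_length: int = 20,
    min_scan_repeats: int = 4,
    n_decoys: int = 0,
    decoy_length: int = 1000,
) -> GenomePair:
    """Two assemblies with planted orthologous repeats and a truth table.

    The i-th planted locus carries ``motif x n_repeats_a`` (genome A) and
    ``motif x n_repeats_b`` (genome B) between identical unique flanks.
    ``flank_mutations > 0`` substitutes that many bases in the B-side 5'
    flank (so the locus cannot be anchored); ``duplicate_flanks`` plants a
    second copy of the B-side cassette (so anchoring is ambiguous). The
    background is free of 3/4-mer runs of >= ``min_scan_repeats`` copies
    and of second occurrences of any flank. Reproducible under ``seed``.
    """
    if not specs:
        raise ValueError("no loci to plant")
    rng = np.random.default_rng(seed)
    n = len(specs)

    cassette_len_a = sum(
        2 * flank_length + len(s.motif) * s.n_repeats_a for s in specs
    )
    seg = (background_length - cassette_len_a) // (n + 1)
    if seg < flank_length + 10:
        raise ValueError("background_length too small for the requested loci")

    for attempt in range(20):
        used: set[str] = set()
        flanks = []
        for s in specs:
            f5 = _make_flank(rng, flank_length, s.motif, "five", used, min_scan_repeats)
            f3 = _make_flank(rng, flank_length, s.motif, "three", used, min_scan_repeats)
            f5b = (
                _mutate_flank(rng, f5, s.flank_mutations, used)
                if s.flank_mutations > 0
                else f5
            )
            flanks.append((f5, f3, f5b))

        def assemble(genome: str) -> tuple[str, list[tuple[int, int, str]]]:
            parts = []
            planted = []  # (start, end, motif) of each repeat tract
            pos = 0
            for s, (f5, f3, f5b) in zip(specs, flanks):
                bg = _clean_seq(rng, seg, min_scan_repeats)
                parts.append(bg)
                pos += len(bg)
                if genome == "A":
                    cas5, n_rep = f5, s.n_repeats_a
                else:
                    cas5, n_rep = f5b, s.n_repeats_b
                repeat = s.motif * n_rep
                parts.extend([cas5, repeat, f3])
                planted.append((pos + len(cas5), pos + len(cas5) + len(repeat), s.motif))
                pos += len(cas5) + len(repeat) + len(f3)
            tail = _clean_seq(rng, seg, min_scan_repeats)
            parts.append(tail)
            pos += len(tail)
            if genome == "B":
                for s, (f5, f3, f5b) in zip(specs, flanks):
                    if s.duplicate_flanks:
                        repeat = s.motif * s.n_repeats_b
                        spacer = _clean_seq(rng, flank_length, min_scan_repeats)
                        parts.extend([spacer, f5b, repeat, f3])
                        pos += len(spacer) + len(f5b) + len(repeat) + len(f3)
            return "".join(parts), planted

        seq_a, planted_a = assemble("A")
        seq_b, _ = assemble("B")

        # junction effects may create unplanned repeats; verify the scan of
        # genome A recovers exactly the planted tracts
        found = {
            (L.start, L.end, L.motif_found): L
            for L in find_repeats(
                Contig("A", seq_a), (3, 4), min_scan_repeats, flank_length
            )
        }
        expected = set(planted_a)
        if set(found) != expected:
            continue
        # every flank (and its reverse complement) must occur the expected
        # number of times in each genome
        ok = True
        for s, (f5, f3, f5b) in zip(specs, flanks):
            dup = 2 if s.duplicate_flanks else 1
            if seq_a.count(f5) != 1 or seq_a.count(f3) != 1:
                ok = False
            if seq_b.count(f5b) != dup or seq_b.count(f3) != dup:
                ok = False
            if s.flank_mutations > 0 and seq_b.count(f5) != 0:
                ok = False
            for f in (f5, f3, f5b):
                if revcomp(f) in seq_a or revcomp(f) in seq_b:
                    ok = False
        if not ok:
            continue

        assembly_a = [Contig("contigA_1", seq_a)]
        assembly_b = [Contig("contigB_1", seq_b)]
        for d in range(n_decoys):
            assembly_a.append(
                Contig(f"decoyA_{d+1}", _clean_seq(rng, decoy_length, min_scan_repeats))
            )
            assembly_b.append(
                Contig(f"decoyB_{d+1}", _clean_seq(rng, decoy_length, min_scan_repeats))
            )

        truth = pd.DataFrame(
            [
                {
                    "locus_id": f"locus_{i:03d}",
                    "motif": s.motif,
                    "motif_canonical": canonical_motif(s.motif),
                    "start_a": planted_a[i][0],
                    "end_a": planted_a[i][1],
                    "n_repeats_a": s.n_repeats_a,
                    "n_repeats_b": s.n_repeats_b,
                    "diff": abs(s.n_repeats_a - s.n_repeats_b),
                    "expected_status": s.expected_status,
                }
                for i, s in enumerate(specs)
            ]
        )
        return GenomePair(assembly_a=assembly_a, assembly_b=assembly_b, truth=truth)
    raise RuntimeError("could not build a collision-free genome pair")


# ---------------------------------------------------------------------------
# Two-population genotype data with controllable divergence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceSpec:
    """Parameters for a two-population genotype dataset.

    ``shared_proportion`` controls the fraction of each locus's alleles that
    are present in both populations' pools; the rest are private, split
    evenly. ``freq_mode`` is ``"random"`` (independent Dirichlet frequencies
    per pool) or ``"identical"`` (one draw shared by both pools; requires
    ``shared_proportion == 1``).
    """

    n_loci: int = 12
    alleles_per_locus: int = 6
    shared_proportion: float = 0.5
    n_a: int = 36
    n_b: int = 36
    seed: Optional[int] = 0
    freq_mode: str = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_proportion <= 1.0:
            raise ValueError("shared_proportion must be in [0, 1]")
        if self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("need at least one locus and one allele")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.freq_mode not in ("random", "identical"):
            raise ValueError("freq_mode must be 'random' or 'identical'")
        if self.freq_mode == "identical" and self.shared_proportion != 1.0:
            raise ValueError("identical frequencies require shared_proportion 1")


def _locus_freqs(
    spec: DivergenceSpec, rng: np.random.Generator
) -> tuple[dict[int, float], dict[int, float]]:
    K = spec.alleles_per_locus
    n_shared = int(round(spec.shared_proportion * K))
    n_priv = K - n_shared
    priv_a = (n_priv + 1) // 2
    priv_b = n_priv - priv_a
    codes = [101 + 2 * j for j in range(K)]
    shared = codes[:n_shared]
    pa = shared + codes[n_shared : n_shared + priv_a]
    pb = shared + codes[n_shared + priv_a :]
    if not pa or not pb:
        raise ValueError(
            f"infeasible spec: a pool has no alleles "
            f"(K={K}, shared_proportion={spec.shared_proportion})"
        )

    def draw(support: list[int]) -> dict[int, float]:
        d = rng.dirichlet(np.full(len(support), 2.0))
        # frequency floor keeps every support allele realistically observable
        f = 0.7 * d + 0.3 / len(support)
        return {a: float(x) for a, x in zip(support, f)}

    fa = draw(pa)
    fb = {a: fa[a] for a in pb} if spec.freq_mode == "identical" else draw(pb)
    if spec.freq_mode == "identical":
        total = sum(fb.values())
        fb = {a: v / total for a, v in fb.items()}
    return fa, fb


def make_genotype_dataset(
    spec: DivergenceSpec,
) -> tuple[GenotypeMatrix, AlleleFreqTable, AlleleFreqTable]:
    """Hardy-Weinberg genotype samples from two diverged allele pools.

    Returns the genotype matrix (populations ``"A"`` and ``"B"``) together
    with the truth frequency tables the genotypes were drawn from.
    """
    rng = np.random.default_rng(spec.seed)
    loci = [f"locus_{i:03d}" for i in range(spec.n_loci)]
    freq_a: dict[str, dict[int, float]] = {}
    freq_b: dict[str, dict[int, float]] = {}
    for locus in loci:
        fa, fb = _locus_freqs(spec, rng)
        freq_a[locus] = fa
        freq_b[locus] = fb

    individuals = [Individual(f"A_{i:04d}", "A") for i in range(spec.n_a)] + [
        Individual(f"B_{i:04d}", "B") for i in range(spec.n_b)
    ]
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for pop, freqs, rows in (
            ("A", freq_a[locus], range(spec.n_a)),
            ("B", freq_b[locus], range(spec.n_a, spec.n_a + spec.n_b)),
        ):
            alleles = np.array(sorted(freqs))
            probs = np.array([freqs[a] for a in alleles])
            probs = probs / probs.sum()
            draws = rng.choice(alleles, size=(len(list(rows)), 2), p=probs)
            calls[list(rows), j, :] = draws
    gm = GenotypeMatrix(individuals=individuals, loci=loci, calls=calls)
    table_a = AlleleFreqTable("A", freq_a, {loc: spec.n_a for loc in loci})
    table_b = AlleleFreqTable("B", freq_b, {loc: spec.n_b for loc in loci})
    return gm, table_a, table_b


# ---------------------------------------------------------------------------
# Synthetic reconstruction of the sparrow diagnostic panel
# ---------------------------------------------------------------------------

# Per-locus summary constraints of the 12-marker panel, as reported for the
# allopatric Saltmarsh (caudacutus) / Nelson's (nelsoni) sparrow samples:
# (total alleles, private alleles, frequency-weighted shared proportion,
#  most-common nelsoni allele, its nelsoni freq, its caudacutus freq,
#  most-common caudacutus allele, its caudacutus freq, its nelsoni freq)
_PANEL_CONSTRAINTS: dict[str, tuple[int, int, float, int, float, float, int, float, float]] = {
    "Ammo001": (9, 6, 0.57, 138, 0.361, 0.00, 118, 0.556, 0.04),
    "Ammo003": (5, 2, 0.93, 154, 0.806, 0.19, 151, 0.471, 0.06),
    "Ammo006": (9, 6, 0.49, 244, 0.403, 0.00, 260, 0.347, 0.00),
    "Ammo008": (4, 1, 0.98, 244, 0.569, 0.01, 250, 0.944, 0.10),
    "Ammo012": (3, 2, 0.11, 177, 0.984, 0.00, 189, 0.803, 0.00),
    "Ammo015": (6, 5, 0.42, 241, 0.972, 0.00, 253, 0.819, 0.03),
    "Ammo016": (6, 2, 0.93, 245, 0.944, 0.03, 257, 0.386, 0.03),
    "Ammo017": (7, 2, 0.95, 116, 0.736, 0.06, 124, 0.583, 0.15),
    "Ammo023": (16, 12, 0.65, 223, 0.403, 0.01, 214, 0.571, 0.01),
    "Ammo027": (10, 6, 0.64, 188, 0.500, 0.10, 212, 0.306, 0.01),
    "Ammo030": (7, 6, 0.59, 264, 0.319, 0.00, 243, 1.00, 0.18),
    "Ammo036": (9, 7, 0.34, 191, 0.764, 0.00, 194, 0.443, 0.03),
}

_MIN_MASS = 0.01


def _reconstruct_locus(
    constraints: tuple[int, int, float, int, float, float, int, float, float],
) -> tuple[dict[int, float], dict[int, float]]:
    (na, n_priv, prop, mc_n, p_n, q_n, mc_c, p_c, q_c) = constraints
    n_shared = na - n_priv

    f_n: dict[int, float] = {mc_n: p_n}
    f_c: dict[int, float] = {mc_c: p_c}
    shared_known = []
    if q_n > 0:
        f_c[mc_n] = q_n
        shared_known.append(mc_n)
    if q_c > 0:
        f_n[mc_c] = q_c
        shared_known.append(mc_c)

    n_unknown = na - 2
    r_sh = max(0, n_shared - len(shared_known))
    r_sh = min(r_sh, n_unknown)
    n_priv_unknown = n_unknown - r_sh

    known_shared_n = sum(f_n[a] for a in shared_known if a in f_n)
    known_shared_c = sum(f_c[a] for a in shared_known if a in f_c)
    u_n = max(0.0, 1.0 - sum(f_n.values()))
    u_c = max(0.0, 1.0 - sum(f_c.values()))

    total_unknown_shared = max(0.0, 2 * prop - known_shared_n - known_shared_c)
    if r_sh == 0:
        s_n = s_c = 0.0
    else:
        s_n = float(np.clip(prop - known_shared_n, _MIN_MASS * r_sh, u_n))
        s_c = float(np.clip(total_unknown_shared - s_n, _MIN_MASS * r_sh, u_c))
        s_n = float(np.clip(total_unknown_shared - s_c, _MIN_MASS * r_sh, u_n))

    m_n = max(0.0, u_n - s_n)
    m_c = max(0.0, u_c - s_c)
    if n_priv_unknown > 0:
        if m_n + m_c <= 0:
            k_n = n_priv_unknown // 2
        else:
            k_n = int(round(n_priv_unknown * m_n / (m_n + m_c)))
        if k_n == 0 and m_n > 2 * _MIN_MASS and n_priv_unknown > 1:
            k_n = 1
        k_c = n_priv_unknown - k_n
        if k_c == 0 and m_c > 2 * _MIN_MASS and n_priv_unknown > 1:
            k_c, k_n = 1, n_priv_unknown - 1
    else:
        k_n = k_c = 0

    code = max(mc_n, mc_c)
    def next_code() -> int:
        nonlocal code
        code += 3
        return code

    for _ in range(r_sh):
        a = next_code()
        f_n[a] = s_n / r_sh
        f_c[a] = s_c / r_sh
    for _ in range(k_n):
        a = next_code()
        f_n[a] = m_n / k_n
    for _ in range(k_c):
        a = next_code()
        f_c[a] = m_c / k_c

    # absorb rounding residue into an unconstrained allele where possible
    # (the most-common-allele frequencies are pinned by the constraints),
    # then normalize
    for f, mc in ((f_n, mc_n), (f_c, mc_c)):
        resid = 1.0 - sum(f.values())
        free = [a for a in f if a not in (mc_n, mc_c)]
        target = max(free, key=lambda a: f[a]) if free else mc
        if free and f[target] + resid >= _MIN_MASS / 2:
            f[target] += resid
        else:
            f[mc] = max(_MIN_MASS / 2, f[mc] + resid)
        total = sum(f.values())
        for a in f:
            f[a] /= total
    return f_n, f_c


def sparrow_panel() -> tuple[AlleleFreqTable, AlleleFreqTable]:
    """Synthetic reconstruction of the 12-locus sparrow panel frequencies.

    Pool A is Nelson's sparrow, pool B is the Saltmarsh sparrow. The
    reconstruction is deterministic and satisfies the reported per-locus
    summary constraints (see module docstring); it is a synthetic stand-in
    for the unpublished per-allele frequency appendix.
    """
    freq_n: dict[str, dict[int, float]] = {}
    freq_c: dict[str, dict[int, float]] = {}
    for locus, cons in _PANEL_CONSTRAINTS.items():
        f_n, f_c = _reconstruct_locus(cons)
        freq_n[locus] = f_n
        freq_c[locus] = f_c
    table_n = AlleleFreqTable("nelsoni", freq_n, {loc: 36 for loc in freq_n})
    table_c = AlleleFreqTable("caudacutus", freq_c, {loc: 36 for loc in freq_c})
    return table_n, table_c
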