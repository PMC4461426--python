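"""Detection of perfect tri- and tetranucleotide microsatellites in contigs.

A microsatellite is reported as one locus per *maximal perfectly periodic
tract*: the longest stretch over which the sequence repeats with period 3 or
4, anchored at the tract start, with ``n_repeats`` full tandem copies of a
primitive motif. Motifs are named by their canonical form, the
lexicographically smallest string among all rotations of the motif and of its
reverse complement, so that e.g. TAA, AAT, ATA, TTA, ATT and TAT all map to
AAT. Loci whose flanking sequence (default 20 bp on each side) runs off the
contig or contains an ambiguous base are kept in the scan output but carry
``None`` flanks and are excluded from cross-genome comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "Contig",
    "RepeatLocus",
    "revcomp",
    "is_primitive",
    "canonical_motif",
    "find_repeats",
    "compute_n50",
    "contigs_above_n50",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence from an assembly."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatLocus:
    """A perfect tandem repeat with its genomic context.

    Coordinates are 0-based, half-open. ``motif_found`` is the motif as it
    occurs on the scanned strand; ``motif_canonical`` is its rotation/
    reverse-complement class representative. ``flank5``/``flank3`` are the
    immediately adjacent sequences of the configured flank length, or ``None``
    when truncated by a contig edge or containing N.
    """

    contig_id: str
    start: int
    end: int
    motif_found: str
    motif_canonical: str
    n_repeats: int
    flank5: Optional[str]
    flank3: Optional[str]

    @property
    def has_flanks(self) -> bool:
        return self.flank5 is not None and self.flank3 is not None


def is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif under rotation and reverse
    complement.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement. Idempotent. Rejects
    motifs that are not primitive 3- or 4-mers over {A,C,G,T}.
    """
    motif = motif.upper()
    if len(motif) not in (3, 4):
        raise ValueError(f"motif length must be 3 or 4, got {motif!r}")
    if not set(motif) <= _VALID:
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"degenerate (non-primitive) motif: {motif!r}")
    variants = []
    for m in (motif, revcomp(motif)):
        for i in range(len(m)):
            variants.append(m[i:] + m[:i])
    return min(variants)


def _tandem_copies(seq: str, i: int, motif: str) -> int:
    """Number of consecutive full copies of ``motif`` starting at ``i``."""
    k = len(motif)
    c = 0
    j = i
    n = len(seq)
    while j + k <= n and seq[j : j + k] == motif:
        c += 1
        j += k
    return c


def find_repeats(
    contig: Contig,
    motif_lengths: Iterable[int] = (3, 4),
    min_repeats: int = 4,
    flank_length: int = 20,
) -> list[RepeatLocus]:
    """Find all maximal perfect tandem repeats of primitive 3/4-mers.

    One locus is reported per maximal periodic tract per period length; the
    locus is anchored at the tract start, so rotated sub-runs of the same
    physical repeat are not reported separately. Loci are returned in
    ascending start order.
    """
    motif_lengths = sorted(set(motif_lengths))
    if not set(motif_lengths) <= {3, 4}:
        raise ValueError("motif lengths must be a subset of {3, 4}")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")

    seq = contig.sequence.upper()
    n = len(seq)
    raw: dict[tuple[int, int], RepeatLocus] = {}
    for k in motif_lengths:
        i = 0
        limit = n - k * min_repeats
        while i <= limit:
            motif = seq[i : i + k]
            if (
                set(motif) <= _VALID
                and is_primitive(motif)
                # tract start: period k does not extend to position i-1
                and (i == 0 or seq[i - 1] != seq[i + k - 1])
            ):
                c = _tandem_copies(seq, i, motif)
                if c >= min_repeats:
                    start, end = i, i + k * c
                    f5 = seq[start - flank_length : start] if start >= flank_length else None
                    f3 = seq[end : end + flank_length] if end + flank_length <= n else None
                    if f5 is not None and "N" in f5:
                        f5 = None
                    if f3 is not None and "N" in f3:
                        f3 = None
                    raw[(start, end)] = RepeatLocus(
                        contig_id=contig.id,
                        start=start,
                        end=end,
                        motif_found=motif,
                        motif_canonical=canonical_motif(motif),
                        n_repeats=c,
                        flank5=f5,
                        flank3=f3,
                    )
                    i = end
                    continue
            i += 1

    # A span claimed under two period lengths is kept under the shorter one
    # (cannot occur for primitive motifs, kept as a guard).
    out = sorted(raw.values(), key=lambda L: (L.start, L.end))
    return out


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50: the length L such that contigs >= L cover half the assembly."""
    if len(contig_lengths) == 0:
        raise ValueError("empty assembly: no contig lengths")
    total = sum(contig_lengths)
    cum = 0
    for length in sorted(contig_lengths, reverse=True):
        cum += length
        if 2 * cum >= total:
            return length
    raise AssertionError("unreachable")


def contigs_above_n50(assembly: Sequence[Contig]) -> list[Contig]:
    """Contigs strictly longer than the assembly's N50, order preserved."""
    n50 = compute_n50([c.length for c in assembly])
    return [c for c in assembly if c.length > n50]
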