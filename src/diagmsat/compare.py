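"""Flank-anchored cross-genome comparison of microsatellite loci.

Each repeat locus detected in a source assembly is located in a target
assembly by exact search for its two flanking sequences, in forward
orientation (5' flank then 3' flank) and in reverse orientation (the reverse
complements in swapped order). A locus matches when both flanks occur exactly
once in the whole target (counting both strands), on the same contig, in the
correct order, with an intervening span below a cap. The repeat count in the
target is the longest tandem run of any rotation of the source motif inside
the orientation-adjusted inter-flank span. Candidate diagnostic loci are then
those whose repeat counts differ between the genomes by an amount inside a
configured band while both genomes carry at least a minimum number of copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .scan import Contig, RepeatLocus, contigs_above_n50, find_repeats, revcomp

__all__ = [
    "MatchStatus",
    "MatchedLocus",
    "FilterBand",
    "match_locus",
    "compare_genomes",
    "apply_diagnostic_filter",
    "status_counts",
]


class MatchStatus(Enum):
    MATCHED = "matched"
    FLANK_MISSING = "flank_missing"
    AMBIGUOUS = "ambiguous"
    SPAN_TOO_LONG = "span_too_long"
    MOTIF_ABSENT = "motif_absent"


@dataclass(frozen=True)
class MatchedLocus:
    """Outcome of locating one source-repeat locus in the target genome."""

    source: RepeatLocus
    status: MatchStatus
    target_contig_id: Optional[str] = None
    target_span: Optional[tuple[int, int]] = None
    orientation: Optional[str] = None  # "forward" | "reverse"
    n_repeats_target: Optional[int] = None
    diff: Optional[int] = None


@dataclass(frozen=True)
class FilterBand:
    """Diagnostic retention band on repeat counts.

    A matched locus is kept when min(n_source, n_target) >=
    ``min_shared_repeats`` and ``diff_min`` <= |n_source - n_target| <=
    ``diff_max``.
    """

    min_shared_repeats: int = 4
    diff_min: int = 3
    diff_max: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.diff_min <= self.diff_max):
            raise ValueError("require 0 <= diff_min <= diff_max")


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _longest_tandem_run(region: str, motif: str) -> int:
    """Longest run of full tandem copies of any rotation of ``motif``."""
    k = len(motif)
    rotations = {motif[i:] + motif[:i] for i in range(k)}
    best = 0
    n = len(region)
    for rot in rotations:
        i = 0
        while i + k <= n:
            if region[i : i + k] == rot:
                c = 1
                j = i + k
                while j + k <= n and region[j : j + k] == rot:
                    c += 1
                    j += k
                best = max(best, c)
                i = j
            else:
                i += 1
    return best


def default_max_span(locus: RepeatLocus, cap: int = 2000) -> int:
    """Default inter-flank span cap: room for 50 motif copies plus flanks."""
    flank = len(locus.flank5 or "") + len(locus.flank3 or "")
    return min(cap, flank + 50 * len(locus.motif_found))


def match_locus(
    locus: RepeatLocus,
    target_assembly: Sequence[Contig],
    max_span: Optional[int] = None,
) -> MatchedLocus:
    """Locate one locus in the target assembly by exact flank search.

    Status taxonomy: a flank absent (or the two flanks not pairable on one
    contig in a consistent orientation) -> ``flank_missing``; any flank seen
    more than once across both strands -> ``ambiguous``; inter-flank span
    above the cap -> ``span_too_long``; flanks anchored but no copy of the
    motif between them -> ``motif_absent``; otherwise ``matched``.
    """
    if not locus.has_flanks:
        return MatchedLocus(source=locus, status=MatchStatus.FLANK_MISSING)
    if max_span is None:
        max_span = default_max_span(locus)

    f5, f3 = locus.flank5, locus.flank3
    rc5, rc3 = revcomp(f5), revcomp(f3)

    occ = {key: [] for key in ("f5", "f3", "rc5", "rc3")}
    for contig in target_assembly:
        seq = contig.sequence.upper()
        for key, pat in (("f5", f5), ("f3", f3), ("rc5", rc5), ("rc3", rc3)):
            for pos in _occurrences(seq, pat):
                occ[key].append((contig.id, pos))

    n5 = len(occ["f5"]) + len(occ["rc5"])
    n3 = len(occ["f3"]) + len(occ["rc3"])
    if n5 > 1 or n3 > 1:
        return MatchedLocus(source=locus, status=MatchStatus.AMBIGUOUS)
    if n5 == 0 or n3 == 0:
        return MatchedLocus(source=locus, status=MatchStatus.FLANK_MISSING)

    contig_by_id = {c.id: c for c in target_assembly}
    fl5, fl3 = len(f5), len(f3)

    if occ["f5"] and occ["f3"]:
        (cid5, p5), (cid3, p3) = occ["f5"][0], occ["f3"][0]
        if cid5 != cid3 or p3 < p5 + fl5:
            return MatchedLocus(source=locus, status=MatchStatus.FLANK_MISSING)
        inner = (p5 + fl5, p3)
        orientation = "forward"
        region = contig_by_id[cid5].sequence.upper()[inner[0] : inner[1]]
        cid = cid5
    elif occ["rc5"] and occ["rc3"]:
        (cid5, q5), (cid3, q3) = occ["rc5"][0], occ["rc3"][0]
        # on the reverse strand the 3' flank's reverse complement comes first
        if cid5 != cid3 or q5 < q3 + fl3:
            return MatchedLocus(source=locus, status=MatchStatus.FLANK_MISSING)
        inner = (q3 + fl3, q5)
        orientation = "reverse"
        region = revcomp(contig_by_id[cid5].sequence.upper()[inner[0] : inner[1]])
        cid = cid5
    else:
        # one flank only found forward, the other only reverse-complemented
        return MatchedLocus(source=locus, status=MatchStatus.FLANK_MISSING)

    if inner[1] - inner[0] > max_span:
        return MatchedLocus(
            source=locus,
            status=MatchStatus.SPAN_TOO_LONG,
        )
    n_target = _longest_tandem_run(region, locus.motif_found)
    if n_target == 0:
        return MatchedLocus(source=locus, status=MatchStatus.MOTIF_ABSENT)
    return MatchedLocus(
        source=locus,
        status=MatchStatus.MATCHED,
        target_contig_id=cid,
        target_span=inner,
        orientation=orientation,
        n_repeats_target=n_target,
        diff=abs(locus.n_repeats - n_target),
    )


def compare_genomes(
    source_assembly: Sequence[Contig],
    target_assembly: Sequence[Contig],
    motif_lengths: Iterable[int] = (3, 4),
    min_repeats: int = 4,
    flank_length: int = 20,
    max_span: Optional[int] = None,
    n50_filter: bool = True,
) -> list[MatchedLocus]:
    """Scan the source assembly and locate every locus in the target.

    When ``n50_filter`` is on, only source contigs strictly longer than the
    assembly N50 are scanned. Every scanned locus yields one record; loci
    whose own flanks are unusable are reported as ``flank_missing``.
    """
    if not source_assembly or not target_assembly:
        raise ValueError("both assemblies must be non-empty")
    contigs = contigs_above_n50(source_assembly) if n50_filter else list(source_assembly)
    results: list[MatchedLocus] = []
    for contig in contigs:
        for locus in find_repeats(
            contig,
            motif_lengths=motif_lengths,
            min_repeats=min_repeats,
            flank_length=flank_length,
        ):
            results.append(match_locus(locus, target_assembly, max_span=max_span))
    return results


def status_counts(matches: Iterable[MatchedLocus]) -> dict[str, int]:
    counts: dict[str, int] = {s.value: 0 for s in MatchStatus}
    for m in matches:
        counts[m.status.value] += 1
    return counts


def apply_diagnostic_filter(
    matches: Sequence[MatchedLocus], band: FilterBand
) -> list[MatchedLocus]:
    """Retain matched loci inside the diagnostic repeat-difference band.

    Input must contain matched records only; order is preserved and the
    output is a subset of the input.
    """
    for m in matches:
        if m.status is not MatchStatus.MATCHED:
            raise ValueError(
                f"non-matched record (status={m.status.value}) in filter input"
            )
    return [
        m
        for m in matches
        if min(m.source.n_repeats, m.n_repeats_target) >= band.min_shared_repeats
        and band.diff_min <= m.diff <= band.diff_max
    ]
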