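"""File formats: FASTA assemblies, GenePop genotype files, TSV tables.

GenePop files are the exchange format for the genotype data: a title line, a
locus list (one name per line or comma-separated on one line), and ``Pop``
blocks of ``id , 001002 003004`` records. Both the 2-digit and 3-digit allele
dialects are read; files are written in the 3-digit dialect. Population
labels are not part of the format, so the reader takes optional names and
otherwise labels blocks ``pop_1``, ``pop_2``, ...
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import MISSING, GenotypeMatrix, Individual
from .scan import Contig, RepeatLocus

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genepop",
    "write_genepop",
    "loci_to_frame",
    "matches_to_frame",
]


def read_fasta(path: PathLike) -> list[Contig]:
    """Read a multi-FASTA assembly into Contig records (uppercased)."""
    return [
        Contig(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(contigs: Iterable[Contig], path: PathLike, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def _parse_allele_token(token: str) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise ValueError(f"malformed diploid allele token {token!r}")
    return int(token[:w]), int(token[w:])


def read_genepop(
    source: Union[PathLike, TextIO],
    pop_names: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Parse a GenePop file into a GenotypeMatrix.

    Handles one-locus-per-line and comma-separated locus headers, and both
    2- and 3-digit allele codes (00/000 = missing).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    lines = [ln.rstrip() for ln in lines]
    if not lines:
        raise ValueError("empty GenePop file")

    # title line is ignored apart from existing
    idx = 1
    loci: list[str] = []
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        chunk = lines[idx].strip()
        if chunk:
            if "," in chunk:
                loci.extend(name.strip() for name in chunk.split(",") if name.strip())
            else:
                loci.append(chunk)
        idx += 1
    if not loci:
        raise ValueError("no locus names before first Pop line")

    individuals: list[Individual] = []
    rows: list[list[tuple[int, int]]] = []
    pop_i = -1
    while idx < len(lines):
        line = lines[idx].strip()
        idx += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_i += 1
            continue
        if pop_i < 0:
            raise ValueError("genotype record before first Pop line")
        if "," not in line:
            raise ValueError(f"malformed individual record {line!r}")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"{ind_id.strip()!r}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        if pop_names is not None:
            label = pop_names[pop_i]
        else:
            label = f"pop_{pop_i + 1}"
        individuals.append(Individual(id=ind_id.strip(), population=label))
        rows.append([_parse_allele_token(t) for t in tokens])

    import numpy as np

    calls = np.array(rows, dtype=np.int64)
    # a half-missing call is treated as fully missing
    half = (calls == MISSING).any(axis=2)
    calls[half] = MISSING
    return GenotypeMatrix(individuals=individuals, loci=loci, calls=calls)


def write_genepop(
    genotypes: GenotypeMatrix,
    path_or_handle: Union[PathLike, TextIO],
    title: str = "diagmsat genotypes",
) -> None:
    """Write a GenotypeMatrix in the 3-digit GenePop dialect.

    Individuals are grouped into Pop blocks by population label, in order of
    first appearance.
    """
    max_code = int(genotypes.calls.max(initial=0))
    if max_code > 999:
        raise ValueError("allele codes exceed the 3-digit GenePop range")
    buf = _io.StringIO()
    buf.write(title + "\n")
    for locus in genotypes.loci:
        buf.write(locus + "\n")
    for pop in genotypes.populations:
        buf.write("Pop\n")
        mask = genotypes.population_mask(pop)
        for ind, row in zip(
            [i for i, m in zip(genotypes.individuals, mask) if m],
            genotypes.calls[mask],
        ):
            tokens = "".join(f" {a:03d}{b:03d}" for a, b in row)
            buf.write(f"{ind.id} ,{tokens}\n")
    text = buf.getvalue()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        Path(path_or_handle).write_text(text)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def loci_to_frame(loci: Iterable[RepeatLocus]) -> pd.DataFrame:
    """Repeat loci as a TSV-ready table (coordinates stay 0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "contig_id": L.contig_id,
                "start": L.start,
                "end": L.end,
                "motif_found": L.motif_found,
                "motif_canonical": L.motif_canonical,
                "n_repeats": L.n_repeats,
                "flank5": L.flank5 or "",
                "flank3": L.flank3 or "",
            }
            for L in loci
        ]
    )


def matches_to_frame(matches) -> pd.DataFrame:
    """MatchedLocus records as a TSV-ready table."""
    rows = []
    for m in matches:
        rows.append(
            {
                "contig_id": m.source.contig_id,
                "start": m.source.start,
                "end": m.source.end,
                "motif_found": m.source.motif_found,
                "motif_canonical": m.source.motif_canonical,
                "status": m.status.value,
                "orientation": m.orientation or "",
                "target_contig_id": m.target_contig_id or "",
                "target_start": -1 if m.target_span is None else m.target_span[0],
                "target_end": -1 if m.target_span is None else m.target_span[1],
                "n_repeats_source": m.source.n_repeats,
                "n_repeats_target": -1 if m.n_repeats_target is None else m.n_repeats_target,
                "diff": -1 if m.diff is None else m.diff,
            }
        )
    return pd.DataFrame(rows)
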