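"""Readers and writers for the pipeline's external formats.

* FASTA genome (indexed access via pyfaidx, or any chrom -> sequence
  mapping such as a plain dict for in-memory fixtures),
* BED3/BED6 occupancy intervals (natively 0-based half-open, passed
  through unshifted),
* tab-separated interaction summary tables (one row per chimeric
  interaction; declared 1-based inclusive, converted once on read).

The interaction-table dialect expected here is a documented projection of
upstream chimeric-read analysis output: a header naming at least
``chrom1 start1 end1 strand1 chrom2 start2 end2 strand2 score``; an
optional ``id`` column supplies record identifiers. ``#`` lines are
comments. Sequences are normalised to the RNA alphabet (T -> U) on
extraction; downstream logic is RNA-only.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, RowError
from .intervals import (
    GenomicInterval,
    RRIRecord,
    dna_to_rna,
    reverse_complement_dna,
)

REQUIRED_COLUMNS = (
    "chrom1",
    "start1",
    "end1",
    "strand1",
    "chrom2",
    "start2",
    "end2",
    "strand2",
    "score",
)


# ---------------------------------------------------------------------------
# genome access


def read_fasta(path):
    """Open a FASTA file for random access."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=False, sequence_always_upper=True)


def chrom_length(genome, chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    return len(genome[chrom])


def chrom_lengths(genome) -> dict[str, int]:
    if isinstance(genome, Mapping):
        return {c: len(genome[c]) for c in genome}
    return {name: len(genome[name]) for name in genome.keys()}


def extract_sequence(genome, interval: GenomicInterval) -> str:
    """RNA sequence of an interval, reverse-complemented for '-' strand.

    ``genome`` may be a pyfaidx.Fasta or any mapping of chromosome name to
    sequence string. T is mapped to U; ambiguity codes are retained (they
    can never base-pair downstream).
    """
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    clen = len(genome[interval.chrom])
    if interval.end > clen:
        raise ValueError(
            f"interval {interval} out of bounds for chromosome "
            f"{interval.chrom} of length {clen}"
        )
    raw = str(genome[interval.chrom][interval.start : interval.end]).upper()
    if interval.strand == "-":
        raw = reverse_complement_dna(raw)
    return dna_to_rna(raw)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# interaction summary tables


def parse_interaction_table(path, replicate_id: str) -> list[RRIRecord]:
    """Read one replicate's interaction summary file.

    Input coordinates are 1-based inclusive; returned records use internal
    0-based half-open coordinates. Row order is preserved.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype=str,
            skip_blank_lines=True,
            na_filter=False,  # "NA" must surface as a parse error, not NaN
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (no header)")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    records: list[RRIRecord] = []
    seen_ids: set[str] = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2  # header is line 1; comments before data are rare
        try:
            score = float(row["score"])
        except (TypeError, ValueError):
            raise RowError(
                f"non-numeric score {row['score']!r}", line_number=line_no
            )
        arms = []
        for side in ("1", "2"):
            try:
                start = int(row[f"start{side}"])
                end = int(row[f"end{side}"])
            except (TypeError, ValueError):
                raise RowError(
                    f"non-integer coordinate in arm {side}", line_number=line_no
                )
            if start > end or start < 1:
                raise RowError(
                    f"arm {side}: invalid 1-based range {start}-{end}",
                    line_number=line_no,
                )
            strand = row[f"strand{side}"]
            if strand not in ("+", "-"):
                raise RowError(
                    f"arm {side}: unknown strand {strand!r}", line_number=line_no
                )
            arms.append(
                GenomicInterval(row[f"chrom{side}"], start - 1, end, strand)
            )
        if score < 0:
            raise RowError(f"negative score {score}", line_number=line_no)
        rid = row["id"] if "id" in df.columns else f"{replicate_id}:{pos}"
        if rid in seen_ids:
            raise RowError(f"duplicate record id {rid!r}", line_number=line_no)
        seen_ids.add(rid)
        records.append(
            RRIRecord(
                arm1=arms[0],
                arm2=arms[1],
                score=score,
                replicate_id=replicate_id,
                record_id=str(rid),
            )
        )
    return records


def write_interaction_table(records: Iterable[RRIRecord], path) -> None:
    """Inverse of :func:`parse_interaction_table` (1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(REQUIRED_COLUMNS) + ["id"])
        for rec in records:
            writer.writerow(
                [
                    rec.arm1.chrom,
                    rec.arm1.start + 1,
                    rec.arm1.end,
                    rec.arm1.strand,
                    rec.arm2.chrom,
                    rec.arm2.start + 1,
                    rec.arm2.end,
                    rec.arm2.strand,
                    repr(rec.score) if rec.score != int(rec.score) else rec.score,
                    rec.record_id,
                ]
            )


# ---------------------------------------------------------------------------
# BED


def parse_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals; strand from column 6 when present, else the
    row is strand-agnostic ('.')."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError("BED row with < 3 columns", line_number=line_no)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise RowError("non-integer BED coordinate", line_number=line_no)
            if start >= end or start < 0:
                raise RowError(
                    f"invalid BED range {start}-{end}", line_number=line_no
                )
            strand = "."
            if len(fields) >= 6:
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise RowError(
                        f"unknown strand symbol {strand!r}", line_number=line_no
                    )
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals, path, origins=None) -> None:
    """Write BED6 (+ optional origin column)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), f"iv{i}", "0", iv.strand]
            if origins is not None:
                row.append(str(origins[i]))
            fh.write("\t".join(row) + "\n")
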