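"""Library of occupied genomic regions.

Regions taking part in any input interaction at a low score cutoff
(default >= 0.5, a deliberately conservative definition of "occupied")
plus optional RNA-binding-protein sites are indexed per chromosome and
strand; duplex prediction later refuses to place base pairs on occupied
positions. Strand-agnostic spans (BED3 rows, crosslink tracks) occupy
both strands; stranded spans occupy their own strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval


def extend_crosslinks(intervals, flank: int, chrom_lengths=None):
    """Widen each interval by ``flank`` nt on both sides (default use:
    single-nucleotide crosslink positions extended 5 nt up- and
    downstream), clipped to the chromosome when lengths are known."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in intervals:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_lengths is not None and iv.chrom in chrom_lengths:
            end = min(chrom_lengths[iv.chrom], end)
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand))
    return out


@dataclass
class OccupiedIndex:
    """Per-chromosome, per-strand interval index over occupied spans.

    Each stored span carries its origin ('rri' or 'rbp') and the set of
    source ids that contributed it; exact duplicates (same span, strand
    and origin) are merged with their source sets unioned.
    """

    _trees: dict = field(default_factory=dict)
    _entries: dict = field(default_factory=dict)

    def add(self, interval: GenomicInterval, origin: str, source: str) -> None:
        strands = ("+", "-") if interval.strand == "." else (interval.strand,)
        for strand in strands:
            key = (interval.chrom, strand, interval.start, interval.end, origin)
            if key in self._entries:
                self._entries[key].add(source)
                continue
            self._entries[key] = {source}
            tree = self._trees.setdefault((interval.chrom, strand), IntervalTree())
            tree.addi(interval.start, interval.end, key)

    def __len__(self) -> int:
        return len(self._entries)

    def query(self, window: GenomicInterval, exclude_sources=frozenset()):
        """Stored spans overlapping the window on its strand.

        Spans whose every source is excluded are skipped (used to hide a
        site's own arms from its positive-instance mask).
        """
        tree = self._trees.get((window.chrom, window.strand))
        if tree is None:
            return []
        hits = []
        for hit in tree.overlap(window.start, window.end):
            sources = self._entries[hit.data]
            if exclude_sources and sources <= exclude_sources:
                continue
            chrom, strand, start, end, origin = hit.data
            hits.append((GenomicInterval(chrom, start, end, strand), origin))
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[1]))
        return hits

    def query_with_sources(self, window: GenomicInterval):
        """Like :meth:`query`, but also yields the source-tag sets."""
        tree = self._trees.get((window.chrom, window.strand))
        if tree is None:
            return []
        hits = []
        for hit in tree.overlap(window.start, window.end):
            chrom, strand, start, end, origin = hit.data
            hits.append(
                (
                    GenomicInterval(chrom, start, end, strand),
                    origin,
                    frozenset(self._entries[hit.data]),
                )
            )
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[1]))
        return hits

    def spans(self):
        """All stored (interval, origin, sources) triples, deterministic order."""
        for key in sorted(self._entries):
            chrom, strand, start, end, origin = key
            yield (
                GenomicInterval(chrom, start, end, strand),
                origin,
                frozenset(self._entries[key]),
            )


def arm_source(record_id: str, arm_no: int) -> str:
    """Source tag of one arm of an interactome record."""
    return f"{record_id}|arm{arm_no}"


def build_occupied_library(
    all_rri_records,
    score_min_occupied: float = 0.5,
    rbp_intervals=(),
) -> OccupiedIndex:
    """Index both arms of every record at score >= cutoff plus all
    (already extended) RBP intervals."""
    index = OccupiedIndex()
    for rec in all_rri_records:
        if rec.score >= score_min_occupied:
            index.add(rec.arm1, "rri", arm_source(rec.record_id, 1))
            index.add(rec.arm2, "rri", arm_source(rec.record_id, 2))
    for i, iv in enumerate(rbp_intervals):
        index.add(iv, "rbp", f"rbp{i}")
    return index


def occupied_mask(
    index: OccupiedIndex,
    window: GenomicInterval,
    exclude_sources=frozenset(),
) -> np.ndarray:
    """Boolean occupancy mask over the window, in window-local,
    strand-oriented order (reversed for '-' windows), so mask[i] aligns
    with position i of the extracted window sequence."""
    mask = np.zeros(len(window), dtype=bool)
    for span, _origin in index.query(window, exclude_sources=exclude_sources):
        lo = max(span.start, window.start) - window.start
        hi = min(span.end, window.end) - window.start
        mask[lo:hi] = True
    if window.strand == "-":
        mask = mask[::-1].copy()
    return mask


def mask_range_local(
    mask: np.ndarray, start_local: int, end_local: int
) -> np.ndarray:
    """Copy of the mask with [start_local, end_local) additionally set."""
    out = mask.copy()
    out[start_local:end_local] = True
    return out
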