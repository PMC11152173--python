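"""Assembly of prediction instances from curated sites.

For each trusted site, both arms are extended by the configured genomic
context (default 150 nt), sequences are extracted strand-oriented,
occupancy masks are laid over the windows (excluding the site's own arms
for the positive prediction), and positive plus negative duplex sets are
predicted.
"""

from __future__ import annotations

import logging

from .config import Config
from .curation import TrustedRRI
from .duplex import PredictionInstance, predict_duplexes
from .intervals import GenomicInterval, RRIRecord, add_context, positions_identifier
from .io import extract_sequence
from .negatives import make_negative_instance
from .occupied import OccupiedIndex, arm_source, occupied_mask

logger = logging.getLogger(__name__)


def local_to_genomic(window: GenomicInterval, local: int) -> int:
    """Genomic position of window-local, strand-oriented index."""
    if window.strand == "-":
        return window.end - 1 - local
    return window.start + local


def _arm_window(arm: GenomicInterval, genome, config: Config):
    clen = len(genome[arm.chrom])
    window, left_offset = add_context(arm, config.context_len, clen)
    if arm.strand == "-":
        core_start = window.end - arm.end
    else:
        core_start = left_offset
    return window, (core_start, core_start + len(arm))


def build_positive_instance(
    arm1: GenomicInterval,
    arm2: GenomicInterval,
    genome,
    occupied_index: OccupiedIndex | None,
    config: Config,
    exclude_sources=frozenset(),
    instance_id: str | None = None,
) -> PredictionInstance:
    """Windows, masks and positive duplex predictions for one site."""
    window1, core1 = _arm_window(arm1, genome, config)
    window2, core2 = _arm_window(arm2, genome, config)
    seq1 = extract_sequence(genome, window1)
    seq2 = extract_sequence(genome, window2)
    if occupied_index is not None:
        mask1 = occupied_mask(occupied_index, window1, exclude_sources)
        mask2 = occupied_mask(occupied_index, window2, exclude_sources)
    else:
        import numpy as np

        mask1 = np.zeros(len(window1), dtype=bool)
        mask2 = np.zeros(len(window2), dtype=bool)
    duplexes = predict_duplexes(
        seq1, seq2, core1, core2, mask1, mask2, config=config, polarity="positive"
    )
    return PredictionInstance(
        instance_id=(instance_id or positions_identifier(arm1, arm2)) + "::pos",
        window1=window1,
        window2=window2,
        seq1=seq1,
        seq2=seq2,
        core1=core1,
        core2=core2,
        mask1=mask1,
        mask2=mask2,
        duplexes=duplexes,
        polarity="positive",
    )


def _own_arm_sources(site: TrustedRRI) -> frozenset:
    sources = set()
    for member in site.members:
        sources.add(arm_source(member.record_id, 1))
        sources.add(arm_source(member.record_id, 2))
    return frozenset(sources)


def build_training_instances(
    trusted: list[TrustedRRI],
    genome,
    occupied_index: OccupiedIndex | None,
    config: Config | None = None,
) -> list[PredictionInstance]:
    """Positive + negative instances for every trusted site.

    A site's own arms (all replicate members) are excluded from the
    positive occupancy mask; for the negative they are re-included in
    full (jittered extents and all) and the cores are masked on top.
    Sites without any positive duplex are kept (flagged, later reported
    NA); negatives without duplexes are dropped with a log entry.
    """
    config = config or Config()
    instances: list[PredictionInstance] = []
    for site in trusted:
        rep = site.representative
        pos = build_positive_instance(
            rep.arm1,
            rep.arm2,
            genome,
            occupied_index,
            config,
            exclude_sources=_own_arm_sources(site),
            instance_id=positions_identifier(rep.arm1, rep.arm2),
        )
        instances.append(pos)
        if not pos.has_prediction:
            logger.info("no positive duplex for %s (NA)", pos.instance_id)
        neg = make_negative_instance(pos, occupied_index, config)
        if neg is not None:
            instances.append(neg)
    return instances


def _self_like_sources(
    occupied_index: OccupiedIndex, arm: GenomicInterval, threshold: float
):
    """Sources of occupied interaction spans that overlap an arm at >= the
    replicate-concordance threshold (relative to the shorter span) — i.e.
    spans that are in all likelihood detections of the same site."""
    from .curation import overlap_fraction

    out = set()
    for span, origin, sources in occupied_index.query_with_sources(arm):
        if origin == "rri" and overlap_fraction(span, arm) >= threshold:
            out |= sources
    return out


def build_eval_instances(
    records: list[RRIRecord],
    genome,
    occupied_index: OccupiedIndex | None,
    config: Config | None = None,
) -> list[PredictionInstance]:
    """Positive-polarity instances for putative sites under evaluation.

    A putative site that itself stems from the interactome behind the
    occupancy library must not be masked by its own detections, so
    occupied interaction spans overlapping either arm at >= the
    concordance overlap threshold are excluded from that site's mask
    (the coordinate-level analogue of the id-based own-arm exclusion
    used during training).
    """
    config = config or Config()
    out = []
    for rec in records:
        exclude = {arm_source(rec.record_id, 1), arm_source(rec.record_id, 2)}
        if occupied_index is not None:
            for arm in (rec.arm1, rec.arm2):
                exclude |= _self_like_sources(
                    occupied_index, arm, config.overlap_threshold
                )
        exclude = frozenset(exclude)
        out.append(
            build_positive_instance(
                rec.arm1,
                rec.arm2,
                genome,
                occupied_index,
                config,
                exclude_sources=exclude,
                instance_id=positions_identifier(rec.arm1, rec.arm2),
            )
        )
    return out


def duplex_genomic_footprint(instance: PredictionInstance):
    """Genomic positions covered by any base pair of any duplex, as a set
    of (chrom, strand, position); used for disjointness audits."""
    footprint = set()
    for d in instance.duplexes:
        for i, j in d.pairs:
            footprint.add(
                (
                    instance.window1.chrom,
                    instance.window1.strand,
                    local_to_genomic(instance.window1, i),
                )
            )
            footprint.add(
                (
                    instance.window2.chrom,
                    instance.window2.strand,
                    local_to_genomic(instance.window2, j),
                )
            )
    return footprint
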