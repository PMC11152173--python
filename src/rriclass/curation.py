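"""Selection of trusted RRI sites from replicated interactome tables.

A site is trusted when it is detected in every replicate (arm-wise overlap
of at least ``overlap_threshold``, default 30%, relative to the shorter
interval) and its representative score passes the reliability cutoff
(default >= 1). Boundary accuracy of detected sites varies between
protocols, so the overlap comparison is deliberately lenient and the
fraction is taken relative to the shorter arm.

Grouping across replicates is greedy one-to-one in descending score with a
coordinate tie-break, so output is deterministic and every input record
supports at most one trusted site. The score filter is applied after
replicate concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import Config
from .intervals import GenomicInterval, RRIRecord


@dataclass(frozen=True)
class TrustedRRI:
    """A replicate-concordant site.

    ``representative`` is the highest-score member of the matched group;
    ``support`` maps replicate id to the matching record ids; ``members``
    keeps the full matched records (needed later to exclude a site's own
    arms from its occupancy mask).
    """

    representative: RRIRecord
    support: dict
    members: tuple

    @property
    def score(self) -> float:
        return self.representative.score


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap of two intervals as a fraction of the shorter one.

    0 for different chromosome or strand; strand '.' matches either.
    """
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    return inter / min(len(a), len(b))


def filter_by_score(records, score_min: float):
    """Keep records with score >= score_min, order preserved."""
    if score_min < 0:
        raise ValueError("score_min must be >= 0")
    return [r for r in records if r.score >= score_min]


def _arms_match(a: RRIRecord, b: RRIRecord, threshold: float) -> bool:
    """Both arms overlap at >= threshold, allowing arm1<->arm2 swap."""
    direct = (
        overlap_fraction(a.arm1, b.arm1) >= threshold
        and overlap_fraction(a.arm2, b.arm2) >= threshold
    )
    if direct:
        return True
    return (
        overlap_fraction(a.arm1, b.arm2) >= threshold
        and overlap_fraction(a.arm2, b.arm1) >= threshold
    )


def _greedy_key(rec: RRIRecord):
    return (-rec.score, rec.sort_key(), rec.record_id)


def filter_by_replicates(
    tables: list[list[RRIRecord]], overlap_threshold: float
) -> list[TrustedRRI]:
    """Keep sites present in all replicates.

    A record of the first replicate seeds a group; it is trusted iff every
    other replicate contributes an unused record whose arms both overlap
    at >= overlap_threshold (swapped arm pairing also tested). Within each
    replicate the best-scoring eligible record joins the group. Records
    are consumed greedily in descending score.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    if len(tables) == 1:
        return [
            TrustedRRI(
                representative=r,
                support={r.replicate_id: [r.record_id]},
                members=(r,),
            )
            for r in tables[0]
        ]

    used = [set() for _ in tables]
    trusted: list[TrustedRRI] = []
    seeds = sorted(tables[0], key=_greedy_key)
    for seed in seeds:
        if seed.record_id in used[0]:
            continue
        group = [seed]
        ok = True
        for t_idx in range(1, len(tables)):
            candidates = [
                r
                for r in tables[t_idx]
                if r.record_id not in used[t_idx]
                and _arms_match(seed, r, overlap_threshold)
            ]
            if not candidates:
                ok = False
                break
            group.append(min(candidates, key=_greedy_key))
        if not ok:
            continue
        for t_idx, member in enumerate(group):
            used[t_idx].add(member.record_id)
        representative = min(group, key=_greedy_key)
        support: dict = {}
        for member in group:
            support.setdefault(member.replicate_id, []).append(member.record_id)
        trusted.append(
            TrustedRRI(
                representative=representative,
                support=support,
                members=tuple(group),
            )
        )
    trusted.sort(key=lambda t: _greedy_key(t.representative))
    return trusted


def curate(
    tables: list[list[RRIRecord]], config: Config | None = None
) -> list[TrustedRRI]:
    """Replicate concordance followed by the score filter."""
    config = config or Config()
    concordant = filter_by_replicates(tables, config.overlap_threshold)
    return [t for t in concordant if t.score >= config.score_min_trusted]
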