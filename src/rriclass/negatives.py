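"""Construction of negative instances.

The negative counterpart of each positive site reuses the site's own
extended windows but masks the site cores themselves (in addition to all
occupied regions), so "flanking" duplexes are predicted from the
remaining genomic context. Negative duplex pairs may not touch the cores
at all and their seeds must be entirely context-resident, which makes
negatives genomically disjoint from every trusted interaction site by
construction while keeping them in close proximity to — and hence
compositionally similar to — the positives.
"""

from __future__ import annotations

import logging

from .config import Config
from .duplex import PredictionInstance, predict_duplexes
from .occupied import OccupiedIndex, mask_range_local, occupied_mask

logger = logging.getLogger(__name__)


def make_negative_instance(
    positive: PredictionInstance,
    occupied_index: OccupiedIndex | None = None,
    config: Config | None = None,
) -> PredictionInstance | None:
    """Build the negative instance of a positive site.

    When the occupancy index is given, masks are rebuilt WITHOUT the
    own-arm exclusion the positive used — the site's own (replicate)
    arms count as occupied for negative generation, including the
    boundary-jittered parts that extend past the representative core.
    The cores themselves are always masked on top.

    Returns None (with a log entry) when the masked context admits no
    duplex at all.
    """
    config = config or Config()
    if occupied_index is not None:
        base1 = occupied_mask(occupied_index, positive.window1)
        base2 = occupied_mask(occupied_index, positive.window2)
    else:
        base1, base2 = positive.mask1, positive.mask2
    mask1 = mask_range_local(base1, *positive.core1)
    mask2 = mask_range_local(base2, *positive.core2)
    if mask1.all() or mask2.all():
        logger.info(
            "negative instance dropped (no unmasked context): %s",
            positive.instance_id,
        )
        return None
    duplexes = predict_duplexes(
        positive.seq1,
        positive.seq2,
        positive.core1,
        positive.core2,
        mask1,
        mask2,
        config=config,
        polarity="negative",
    )
    if not duplexes:
        logger.info(
            "negative instance dropped (no legal flanking duplex): %s",
            positive.instance_id,
        )
        return None
    return PredictionInstance(
        instance_id=positive.instance_id + "::neg",
        window1=positive.window1,
        window2=positive.window2,
        seq1=positive.seq1,
        seq2=positive.seq2,
        core1=positive.core1,
        core2=positive.core2,
        mask1=mask1,
        mask2=mask2,
        duplexes=duplexes,
        polarity="negative",
    )
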