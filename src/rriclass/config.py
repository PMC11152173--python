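"""Pipeline configuration.

The loop penalty of the internal energy model is deliberately larger
than the magnitude of a single pair energy (default 3.0 per unpaired
nucleotide vs −2.0 for a GC pair): gapped extension must then be paid
for by genuinely complementary continuation, so optimal duplexes are
compact helices anchored at the detected site rather than arbitrarily
long low-density "staircases" whose energy would otherwise grow with
window length alone.

Every tunable constant of the pipeline lives here, with the defaults used
throughout: replicate-concordance overlap threshold 30%, trusted-site score
cutoff 1.0, occupied-region score cutoff 0.5, 150-nt genomic context, seeds
of 5 consecutive base pairs, up to 5 suboptimal duplexes per site, and
crosslink extension of 5 nt up- and downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict


DEFAULT_PAIR_ENERGIES = {"GC": -2.0, "AU": -1.0, "GU": -0.5}


@dataclass
class Config:
    # curation
    overlap_threshold: float = 0.30
    score_min_trusted: float = 1.0
    # occupancy
    score_min_occupied: float = 0.5
    crosslink_flank: int = 5
    # duplex prediction
    context_len: int = 150
    seed_len: int = 5
    n_suboptimals: int = 5
    max_loop: int = 3
    loop_penalty: float = 3.0
    pair_energies: dict = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    # graph-kernel features
    graph_radius: int = 2
    graph_distance: int = 4
    hash_bits: int = 16
    # model selection
    importance_cutoff: float = 1e-4
    cv_folds: int = 5
    search_iters: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.context_len < 0:
            raise ValueError("context_len must be >= 0")
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if self.n_suboptimals < 1:
            raise ValueError("n_suboptimals must be >= 1")
        if not (8 <= self.hash_bits <= 28):
            raise ValueError("hash_bits must be in [8, 28]")

    def fingerprint(self) -> str:
        """Stable hash of every setting that changes pipeline output.

        The RNG seed is excluded: models trained with different seeds on
        the same settings stay comparable at eval time.
        """
        payload = asdict(self)
        payload.pop("rng_seed")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
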