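"""Synthetic interactome fixtures with known ground truth.

Emulates the inputs of a direct-duplex-detection study processed by an
upstream chimeric-read pipeline: a random genome; replicated interaction
tables containing planted complementary site pairs re-detected in every
replicate with independent boundary jitter and per-replicate scores;
decoy rows (spurious chimeras at random, replicate-inconsistent
positions with low scores); and optional RNA-binding-protein BED tracks.

Planted site pairs are written into the genome as reverse-complementary
segments mutated at a configurable rate. The *energy-matched* fixture
variant additionally plants a context decoy per site: a complementary
segment pair in the flanking context whose optimal duplex energy is
matched to the site's own by rejection sampling on the internal energy
model, but drawn from a different base composition. In that variant the
negative instances generated from the context carry energies
indistinguishable from the positives — a stability-only classifier is
uninformative by construction — while composition and length features
remain informative.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .config import Config
from .duplex import predict_duplexes
from .intervals import GenomicInterval, RRIRecord, reverse_complement_dna

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth of one planted interaction."""

    site_a: GenomicInterval
    site_b: GenomicInterval
    n_mutations: int
    flank_a: GenomicInterval | None
    flank_b: GenomicInterval | None
    flank_mutations: int
    record_ids: dict  # replicate_id -> record id


@dataclass
class SyntheticTruth:
    pairs: list
    n_replicates: int
    boundary_jitter: int
    n_decoys: int
    seed: int
    decoy_ids: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pairs)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_genome(
    n_chrom: int = 2,
    length: int = 100_000,
    gc_bias: float = 0.5,
    seed: int = 0,
) -> dict:
    """Random DNA genome as a chrom -> sequence dict (i.i.d. bases at the
    stated GC fraction), deterministic per seed."""
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    return {
        f"chr{c + 1}": _random_seq(rng, length, gc_bias)
        for c in range(n_chrom)
    }


def generate_rbp_bed(
    genome: dict, n_sites: int, len_range=(10, 30), seed: int = 0
) -> list:
    """Random stranded intervals emulating protein-binding sites."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    out = []
    for _ in range(n_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, len(genome[chrom]) - ln))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(GenomicInterval(chrom, start, start + ln, strand))
    return out


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute n_mut distinct positions with a different random base."""
    if n_mut == 0:
        return seq
    arr = list(seq)
    positions = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    for pos in positions:
        options = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = options[int(rng.integers(3))]
    return "".join(arr)


def _write_oriented(
    genome: dict,
    chrom: str,
    strand: str,
    window_start: int,
    window_end: int,
    local_start: int,
    seq: str,
) -> GenomicInterval:
    """Overwrite genome so the given window-local, strand-oriented
    position carries ``seq`` (given 5'->3' in window orientation)."""
    if strand == "+":
        gstart = window_start + local_start
        payload = seq
    else:
        gstart = window_end - local_start - len(seq)
        payload = reverse_complement_dna(seq)
    s = genome[chrom]
    genome[chrom] = s[:gstart] + payload + s[gstart + len(payload) :]
    return GenomicInterval(chrom, gstart, gstart + len(seq), strand)


def _rna(seq: str) -> str:
    return seq.replace("T", "U")


def duplex_min_energy(seq_a: str, seq_b: str, config: Config) -> float | None:
    """Optimal internal duplex energy of two (DNA-alphabet) segments."""
    cfg = dc_replace(config, n_suboptimals=1)
    hits = predict_duplexes(
        _rna(seq_a),
        _rna(seq_b),
        (0, len(seq_a)),
        (0, len(seq_b)),
        None,
        None,
        config=cfg,
        polarity="positive",
    )
    return hits[0].energy if hits else None


def _energy_matched_complement(
    rng: np.random.Generator,
    length: int,
    gc: float,
    target_energy: float,
    config: Config,
    max_mut: int = 14,
):
    """A complementary segment pair whose optimal duplex energy matches
    ``target_energy`` as closely as mutation count allows (rejection on
    the internal energy model)."""
    fwd = _random_seq(rng, length, gc)
    mut_positions = rng.permutation(length)
    best = None
    perfect = reverse_complement_dna(fwd)
    current = list(perfect)
    for m in range(max_mut + 1):
        if m > 0:
            pos = mut_positions[m - 1]
            options = [b for b in "ACGT" if b != current[pos]]
            current[pos] = options[int(rng.integers(3))]
        energy = duplex_min_energy(fwd, "".join(current), config)
        if energy is None:
            break
        gap = abs(energy - target_energy)
        if best is None or gap < best[0]:
            best = (gap, fwd, "".join(current), m)
        if energy > target_energy:
            break
    if best is None:  # no seed even unmutated; caller retries
        return None
    return best[1], best[2], best[3]


def plant_interactome(
    genome: dict,
    n_sites: int = 150,
    site_len_range=(20, 40),
    mutation_rate: float = 0.10,
    n_replicates: int = 3,
    boundary_jitter: int = 5,
    score_range=(1.0, 8.0),
    n_decoys: int = 50,
    decoy_score_range=(0.05, 0.9),
    site_gc: float = 0.65,
    flank_gc: float = 0.45,
    plant_flank_decoys: bool = False,
    config: Config | None = None,
    seed: int = 0,
):
    """Plant complementary site pairs and emit replicate tables.

    Returns (mutated genome, list of per-replicate record lists, truth).
    Sites are laid out in disjoint slots wide enough that extended
    windows never overlap another planted site; decoy rows are drawn from
    the unused slots, independently per replicate.
    """
    config = config or Config()
    rng = np.random.default_rng(seed)
    genome = dict(genome)
    ctx = config.context_len
    site_max = site_len_range[1]
    slot_w = 2 * (ctx + boundary_jitter) + site_max + 30
    slots = []
    for chrom in sorted(genome):
        clen = len(genome[chrom])
        for s in range(10, clen - slot_w, slot_w):
            slots.append((chrom, s))
    if len(slots) < 2 * n_sites + 2:
        raise ValueError(
            f"genome too small: {len(slots)} slots for {2 * n_sites} site arms"
        )
    order = rng.permutation(len(slots))
    arm_slots = [slots[i] for i in order[: 2 * n_sites]]
    free_slots = [slots[i] for i in order[2 * n_sites :]]

    pairs: list[PlantedPair] = []
    replicate_records: list[list] = [[] for _ in range(n_replicates)]
    rep_ids = [f"rep{r + 1}" for r in range(n_replicates)]

    for k in range(n_sites):
        ln = int(rng.integers(site_len_range[0], site_len_range[1] + 1))
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_b = "+" if rng.random() < 0.5 else "-"
        chrom_a, slot_a = arm_slots[2 * k]
        chrom_b, slot_b = arm_slots[2 * k + 1]
        core_a = _random_seq(rng, ln, site_gc)
        n_mut = int(rng.binomial(ln, mutation_rate))
        core_b = _mutate(rng, reverse_complement_dna(core_a), n_mut)

        arm_start_a = slot_a + ctx + boundary_jitter + 5
        arm_start_b = slot_b + ctx + boundary_jitter + 5
        win_a = (arm_start_a - ctx, arm_start_a + ln + ctx)
        win_b = (arm_start_b - ctx, arm_start_b + ln + ctx)
        site_a = _write_oriented(
            genome, chrom_a, strand_a, win_a[0], win_a[1], ctx, core_a
        )
        site_b = _write_oriented(
            genome, chrom_b, strand_b, win_b[0], win_b[1], ctx, core_b
        )

        flank_a = flank_b = None
        flank_mut = 0
        if plant_flank_decoys:
            target = duplex_min_energy(core_a, core_b, config)
            if target is None:
                target = -2.0 * ln * site_gc  # perfect-complement scale
            lf = int(
                np.clip(
                    ln + rng.integers(-5, 6), 15, site_len_range[1] + 5
                )
            )
            matched = _energy_matched_complement(
                rng, lf, flank_gc, target, config
            )
            if matched is not None:
                f_fwd, f_rev, flank_mut = matched
                side_a = rng.random() < 0.5
                side_b = rng.random() < 0.5
                gap_a = int(rng.integers(30, 71))
                gap_b = int(rng.integers(30, 71))
                la = ctx + ln + gap_a if side_a else ctx - gap_a - lf
                lb = ctx + ln + gap_b if side_b else ctx - gap_b - lf
                flank_a = _write_oriented(
                    genome, chrom_a, strand_a, win_a[0], win_a[1], la, f_fwd
                )
                flank_b = _write_oriented(
                    genome, chrom_b, strand_b, win_b[0], win_b[1], lb, f_rev
                )

        record_ids = {}
        for r in range(n_replicates):
            arms = []
            for site in (site_a, site_b):
                ds = int(rng.integers(-boundary_jitter, boundary_jitter + 1))
                de = int(rng.integers(-boundary_jitter, boundary_jitter + 1))
                start = max(0, site.start + ds)
                end = min(len(genome[site.chrom]), site.end + de)
                if end - start < 8:
                    start, end = site.start, site.end
                arms.append(GenomicInterval(site.chrom, start, end, site.strand))
            score = float(rng.uniform(*score_range))
            rid = f"{rep_ids[r]}:p{k}"
            record_ids[rep_ids[r]] = rid
            replicate_records[r].append(
                RRIRecord(
                    arm1=arms[0],
                    arm2=arms[1],
                    score=score,
                    replicate_id=rep_ids[r],
                    record_id=rid,
                )
            )
        pairs.append(
            PlantedPair(
                site_a=site_a,
                site_b=site_b,
                n_mutations=n_mut,
                flank_a=flank_a,
                flank_b=flank_b,
                flank_mutations=flank_mut,
                record_ids=record_ids,
            )
        )

    decoy_ids: dict = {}
    for r in range(n_replicates):
        ids = []
        for d in range(n_decoys):
            arms = []
            for _ in range(2):
                chrom, slot = free_slots[int(rng.integers(len(free_slots)))]
                ln = int(rng.integers(site_len_range[0], site_len_range[1] + 1))
                start = slot + int(rng.integers(0, slot_w - ln))
                strand = "+" if rng.random() < 0.5 else "-"
                arms.append(GenomicInterval(chrom, start, start + ln, strand))
            rid = f"{rep_ids[r]}:d{d}"
            ids.append(rid)
            replicate_records[r].append(
                RRIRecord(
                    arm1=arms[0],
                    arm2=arms[1],
                    score=float(rng.uniform(*decoy_score_range)),
                    replicate_id=rep_ids[r],
                    record_id=rid,
                )
            )
        decoy_ids[rep_ids[r]] = ids
        perm = rng.permutation(len(replicate_records[r]))
        replicate_records[r] = [replicate_records[r][i] for i in perm]

    truth = SyntheticTruth(
        pairs=pairs,
        n_replicates=n_replicates,
        boundary_jitter=boundary_jitter,
        n_decoys=n_decoys,
        seed=seed,
        decoy_ids=decoy_ids,
    )
    return genome, replicate_records, truth


@dataclass
class FixtureBundle:
    genome: dict
    replicates: list
    truth: SyntheticTruth
    config: Config


def default_fixture(
    seed: int = 0,
    n_sites: int = 150,
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    config: Config | None = None,
    **plant_kwargs,
) -> FixtureBundle:
    """The default study fixture: 2 chromosomes x 100 kb, 150 planted
    pairs, 3 replicates, 10% mutation, boundary jitter 5."""
    config = config or Config(rng_seed=seed)
    genome = generate_genome(
        n_chrom=n_chrom, length=chrom_len, gc_bias=0.5, seed=seed
    )
    genome, replicates, truth = plant_interactome(
        genome, n_sites=n_sites, config=config, seed=seed + 1, **plant_kwargs
    )
    return FixtureBundle(
        genome=genome, replicates=replicates, truth=truth, config=config
    )


def energy_matched_fixture(
    seed: int = 0,
    n_sites: int = 150,
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    config: Config | None = None,
    **plant_kwargs,
) -> FixtureBundle:
    """Default fixture plus energy-matched context decoys: every site's
    flanks carry a planted complementary pair whose duplex energy is
    rejection-matched to the site's own, so a stability-only ranking of
    positive vs negative instances is uninformative by construction."""
    return default_fixture(
        seed=seed,
        n_sites=n_sites,
        n_chrom=n_chrom,
        chrom_len=chrom_len,
        config=config,
        plant_flank_decoys=True,
        **plant_kwargs,
    )
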