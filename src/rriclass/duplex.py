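"""Seed-anchored, occupancy-masked intermolecular duplex prediction.

Given the two extended windows of a candidate interaction site, this
module predicts up to ``n_suboptimals`` intermolecular duplexes under a
simplified additive energy model: each legal base pair (GC, AU, GU and
their reverses) contributes a fixed negative energy and every unpaired
nucleotide enclosed between consecutive pairs costs a linear loop
penalty. Duplexes are antiparallel chains of pairs (positions strictly
increasing on side 1, strictly decreasing on side 2) with at most
``max_loop`` unpaired nucleotides between consecutive pairs on each side,
terminated by pairs on both ends.

Every reported duplex must contain a *seed*: ``seed_len`` consecutive
(gap-free) pairs whose positions all lie inside the experimentally
detected site cores (positive instances) or entirely outside them
(negative instances). Pairs may never sit on occupancy-masked positions,
while the duplex as a whole may extend past the cores into the genomic
context.

The search is exact: a backward dynamic program over pair states
augmented with the current seed-run length and a seeded flag yields, for
every state, the exact best-completion energy; best-first enumeration
with that bound then emits duplexes in nondecreasing energy with a
deterministic tie-break (lexicographically smallest pair list). The k
reported duplexes are exactly the k best distinct-by-pair-set duplexes
satisfying all constraints.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .intervals import GenomicInterval

_PAIR_TYPE = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}


def pair_type(b1: str, b2: str) -> str | None:
    """Canonical pair class of two RNA bases, or None if they cannot pair.
    Ambiguity codes (N, ...) never pair."""
    return _PAIR_TYPE.get((b1, b2))


@dataclass(frozen=True)
class Duplex:
    """One predicted intermolecular base pairing.

    ``pairs`` are (i, j) window-local indices, i strictly increasing and j
    strictly decreasing (antiparallel). ``seed`` is (index into pairs of
    the first maximal seed run, run length). Lower energy = more stable.
    """

    pairs: tuple
    energy: float
    seed: tuple
    rank: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def span1(self) -> tuple:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    def span2(self) -> tuple:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)


@dataclass
class PredictionInstance:
    """One training/eval instance: the two extended windows of a site,
    the local core ranges of the original site, occupancy masks, and the
    predicted duplexes."""

    instance_id: str
    window1: GenomicInterval
    window2: GenomicInterval
    seq1: str
    seq2: str
    core1: tuple
    core2: tuple
    mask1: np.ndarray
    mask2: np.ndarray
    duplexes: list = field(default_factory=list)
    polarity: str = "positive"

    @property
    def has_prediction(self) -> bool:
        return len(self.duplexes) > 0

    def min_energy(self) -> float:
        return min(d.energy for d in self.duplexes)


# ---------------------------------------------------------------------------
# matrices


def pair_matrices(seq1, seq2, mask1, mask2, pair_energies):
    """Legality matrix P and energy matrix E (+inf where illegal or
    masked) over all (i, j) position pairs."""
    n1, n2 = len(seq1), len(seq2)
    P = np.zeros((n1, n2), dtype=bool)
    E = np.full((n1, n2), np.inf)
    for i, b1 in enumerate(seq1):
        if mask1 is not None and mask1[i]:
            continue
        for j, b2 in enumerate(seq2):
            if mask2 is not None and mask2[j]:
                continue
            pt = _PAIR_TYPE.get((b1, b2))
            if pt is not None:
                P[i, j] = True
                E[i, j] = pair_energies[pt]
    return P, E


def _in_range(idx, rng) -> bool:
    return rng[0] <= idx < rng[1]


def seed_eligibility(P, core1, core2, polarity: str):
    """Pairs on which a seed may sit: inside both cores for positive
    instances, entirely outside both cores for negative instances."""
    n1, n2 = P.shape
    in1 = np.zeros(n1, dtype=bool)
    in1[core1[0] : core1[1]] = True
    in2 = np.zeros(n2, dtype=bool)
    in2[core2[0] : core2[1]] = True
    if polarity == "positive":
        region = np.outer(in1, in2)
    elif polarity == "negative":
        region = np.outer(~in1, ~in2)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return P & region


def find_seeds(seq1, seq2, core1, core2, mask1, mask2, seed_len: int,
               pair_energies=None, polarity: str = "positive"):
    """Exhaustive list of seed candidates: ``seed_len`` consecutive legal
    antiparallel pairs, all positions seed-eligible and unmasked, ordered
    by (i, j) of the first pair."""
    pair_energies = pair_energies or Config().pair_energies
    P, _ = pair_matrices(seq1, seq2, mask1, mask2, pair_energies)
    S = seed_eligibility(P, core1, core2, polarity)
    n1, n2 = S.shape
    seeds = []
    for i in range(n1 - seed_len + 1):
        for j in range(seed_len - 1, n2):
            if all(S[i + t, j - t] for t in range(seed_len)):
                seeds.append(tuple((i + t, j - t) for t in range(seed_len)))
    return seeds


def duplex_energy(pairs, seq1, seq2, config: Config | None = None) -> float:
    """Recompute the additive energy of a pair list: sum of pair energies
    plus loop_penalty per enclosed unpaired nucleotide on either side."""
    config = config or Config()
    if not pairs:
        raise ValueError("empty pair list")
    energy = 0.0
    for t, (i, j) in enumerate(pairs):
        pt = _PAIR_TYPE.get((seq1[i], seq2[j]))
        if pt is None:
            raise ValueError(f"illegal pair {seq1[i]}-{seq2[j]} at {(i, j)}")
        energy += config.pair_energies[pt]
        if t > 0:
            pi, pj = pairs[t - 1]
            g1 = i - pi - 1
            g2 = pj - j - 1
            if g1 < 0 or g2 < 0:
                raise ValueError("pairs not antiparallel-ordered")
            energy += config.loop_penalty * (g1 + g2)
    return energy


# ---------------------------------------------------------------------------
# exact best-completion bound


def _completion_bound(P, E, S, seed_len, max_loop, loop_penalty):
    """b[i, j, r, s]: exact minimum additional energy to complete a duplex
    whose last pair is (i, j), where r is the current (capped) length of
    the running gap-free seed-eligible pair run and s flags whether a full
    seed has already occurred. Termination costs 0 and is only allowed
    from seeded states."""
    n1, n2 = P.shape
    L = seed_len
    b = np.full((n1, n2, L + 1, 2), np.inf)
    b[:, :, :, 1] = 0.0
    for i in range(n1 - 1, -1, -1):
        cur = b[i]
        for g1 in range(max_loop + 1):
            i2 = i + 1 + g1
            if i2 >= n1:
                break
            for g2 in range(max_loop + 1):
                shift = 1 + g2
                if shift >= n2 + 1:
                    break
                width = n2 - shift
                if width <= 0:
                    continue
                e2 = E[i2, :width]
                S2 = S[i2, :width]
                bnext = b[i2, :width]
                if g1 == 0 and g2 == 0:
                    for r in range(L + 1):
                        r2 = min(r + 1, L)
                        for s in (0, 1):
                            s2e = 1 if (s == 1 or r2 == L) else 0
                            v = e2 + np.where(
                                S2, bnext[:, r2, s2e], bnext[:, 0, s]
                            )
                            np.minimum(cur[shift:, r, s], v, out=cur[shift:, r, s])
                else:
                    lc = loop_penalty * (g1 + g2)
                    for s in (0, 1):
                        s2e = 1 if (s == 1 or L == 1) else 0
                        v = e2 + lc + np.where(
                            S2, bnext[:, min(1, L), s2e], bnext[:, 0, s]
                        )
                        np.minimum(
                            cur[shift:, :, s], v[:, None], out=cur[shift:, :, s]
                        )
    return b


def _seed_annotation(pairs, S, seed_len):
    """(index of first pair of the first maximal seed run, run length)."""
    runs = []
    run_start, run_len = 0, 0
    for t, (i, j) in enumerate(pairs):
        stacked = (
            t > 0
            and i == pairs[t - 1][0] + 1
            and j == pairs[t - 1][1] - 1
        )
        if S[i, j]:
            if run_len > 0 and stacked:
                run_len += 1
            else:
                run_start, run_len = t, 1
        else:
            run_len = 0
        if run_len >= seed_len:
            nxt = t + 1
            extend = run_len
            while nxt < len(pairs):
                ni, nj = pairs[nxt]
                if (
                    ni == pairs[nxt - 1][0] + 1
                    and nj == pairs[nxt - 1][1] - 1
                    and S[ni, nj]
                ):
                    extend += 1
                    nxt += 1
                else:
                    break
            return (run_start, extend)
    return None


def predict_duplexes(
    seq1,
    seq2,
    core1,
    core2,
    mask1,
    mask2,
    config: Config | None = None,
    polarity: str = "positive",
    max_pops: int = 2_000_000,
):
    """Top ``n_suboptimals`` seed-containing duplexes, energy-ascending.

    Returns a (possibly empty) list of :class:`Duplex`, pairwise distinct
    in base-pair sets, deterministic under the documented tie-break.
    """
    config = config or Config()
    n1, n2 = len(seq1), len(seq2)
    if n1 == 0 or n2 == 0:
        return []
    if mask1 is None:
        mask1 = np.zeros(n1, dtype=bool)
    if mask2 is None:
        mask2 = np.zeros(n2, dtype=bool)
    L = config.seed_len
    ml = config.max_loop
    lp = config.loop_penalty

    P, E = pair_matrices(seq1, seq2, mask1, mask2, config.pair_energies)
    if not P.any():
        return []
    S = seed_eligibility(P, core1, core2, polarity)
    if not S.any():
        return []
    b = _completion_bound(P, E, S, L, ml, lp)

    heap = []
    ii, jj = np.nonzero(P)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if S[i, j]:
            r0 = min(1, L)
            s0 = 1 if L == 1 else 0
        else:
            r0, s0 = 0, 0
        f0 = E[i, j] + b[i, j, r0, s0]
        if np.isfinite(f0):
            heap.append((f0, ((i, j),), False, i, j, r0, s0, float(E[i, j])))
    heapq.heapify(heap)

    results: list[Duplex] = []
    k = config.n_suboptimals
    pops = 0
    while heap and len(results) < k and pops < max_pops:
        f, pairs, complete, i, j, r, s, g = heapq.heappop(heap)
        pops += 1
        if complete:
            seed = _seed_annotation(pairs, S, L)
            assert seed is not None, "completed path without a seed"
            results.append(
                Duplex(pairs=pairs, energy=g, seed=seed, rank=len(results) + 1)
            )
            continue
        if s == 1:
            heapq.heappush(heap, (g, pairs, True, i, j, r, s, g))
        for g1 in range(ml + 1):
            i2 = i + 1 + g1
            if i2 >= n1:
                break
            for g2 in range(ml + 1):
                j2 = j - 1 - g2
                if j2 < 0:
                    break
                if not P[i2, j2]:
                    continue
                if S[i2, j2]:
                    r2 = min(r + 1, L) if (g1 == 0 and g2 == 0) else min(1, L)
                    s2 = 1 if (s == 1 or r2 == L) else 0
                else:
                    r2, s2 = 0, s
                g_new = g + float(E[i2, j2]) + lp * (g1 + g2)
                f_new = g_new + b[i2, j2, r2, s2]
                if np.isfinite(f_new):
                    heapq.heappush(
                        heap,
                        (f_new, pairs + ((i2, j2),), False, i2, j2, r2, s2, g_new),
                    )
    return results


# ---------------------------------------------------------------------------
# validation of emitted duplexes (constraint re-check)


def validate_duplex(
    duplex: Duplex,
    seq1,
    seq2,
    core1,
    core2,
    mask1,
    mask2,
    config: Config,
    polarity: str = "positive",
) -> list:
    """Re-validate every structural invariant of an emitted duplex.

    Returns a list of human-readable violations (empty = valid): legal
    unmasked pairs, antiparallel order, loop limits, a seed of
    ``seed_len`` consecutive pairs in the required region, and stored
    energy equal to recomputation.
    """
    problems = []
    pairs = duplex.pairs
    if not pairs:
        return ["empty duplex"]
    for t, (i, j) in enumerate(pairs):
        if not (0 <= i < len(seq1) and 0 <= j < len(seq2)):
            problems.append(f"pair {(i, j)} out of bounds")
            continue
        if _PAIR_TYPE.get((seq1[i], seq2[j])) is None:
            problems.append(f"illegal pair {seq1[i]}-{seq2[j]} at {(i, j)}")
        if (mask1 is not None and mask1[i]) or (mask2 is not None and mask2[j]):
            problems.append(f"pair {(i, j)} on masked position")
        if t > 0:
            pi, pj = pairs[t - 1]
            if not (i > pi and j < pj):
                problems.append(f"pairs not antiparallel at index {t}")
            elif (i - pi - 1) > config.max_loop or (pj - j - 1) > config.max_loop:
                problems.append(f"loop limit exceeded before pair {(i, j)}")
        if polarity == "negative" and (
            _in_range(i, core1) or _in_range(j, core2)
        ):
            problems.append(f"negative-instance pair {(i, j)} touches a core")
    # seed
    P = np.zeros((len(seq1), len(seq2)), dtype=bool)
    for i, j in pairs:
        if 0 <= i < len(seq1) and 0 <= j < len(seq2):
            P[i, j] = True
    S = seed_eligibility(P, core1, core2, polarity)
    if _seed_annotation(pairs, S, config.seed_len) is None:
        problems.append("no valid seed run")
    try:
        recomputed = duplex_energy(pairs, seq1, seq2, config)
        if abs(recomputed - duplex.energy) > 1e-9:
            problems.append(
                f"energy mismatch: stored {duplex.energy}, recomputed {recomputed}"
            )
    except ValueError as exc:
        problems.append(f"energy recomputation failed: {exc}")
    return problems
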