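"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code path with the
package: exhaustive recursion instead of dynamic programming, linear
scans instead of interval trees, literal per-feature recomputation
instead of the feature builder.
"""

from __future__ import annotations

import math
from collections import Counter

from rriclass.duplex import pair_type

PAIR_E = {"GC": -2.0, "AU": -1.0, "GU": -0.5}


def enumerate_duplexes(
    seq1,
    seq2,
    core1,
    core2,
    mask1,
    mask2,
    seed_len,
    max_loop,
    loop_penalty,
    pair_energies=None,
    polarity="positive",
):
    """Every valid duplex (pair chain) by exhaustive recursion.

    Returns a list of (energy, pairs) for every antiparallel chain of
    legal unmasked pairs obeying the loop limit and containing at least
    one run of ``seed_len`` consecutive seed-eligible pairs.
    """
    pair_energies = pair_energies or PAIR_E
    n1, n2 = len(seq1), len(seq2)

    def masked(i, j):
        return (mask1 is not None and mask1[i]) or (
            mask2 is not None and mask2[j]
        )

    def legal(i, j):
        return pair_type(seq1[i], seq2[j]) is not None and not masked(i, j)

    def eligible(i, j):
        in1 = core1[0] <= i < core1[1]
        in2 = core2[0] <= j < core2[1]
        if polarity == "positive":
            return in1 and in2
        return (not in1) and (not in2)

    out = []

    def extend(chain, energy, run, seeded):
        if seeded:
            out.append((energy, tuple(chain)))
        i, j = chain[-1]
        for g1 in range(max_loop + 1):
            for g2 in range(max_loop + 1):
                i2, j2 = i + 1 + g1, j - 1 - g2
                if i2 >= n1 or j2 < 0 or not legal(i2, j2):
                    continue
                if eligible(i2, j2):
                    run2 = run + 1 if (g1 == 0 and g2 == 0) else 1
                else:
                    run2 = 0
                e2 = (
                    energy
                    + pair_energies[pair_type(seq1[i2], seq2[j2])]
                    + loop_penalty * (g1 + g2)
                )
                extend(chain + [(i2, j2)], e2, run2, seeded or run2 >= seed_len)

    for i in range(n1):
        for j in range(n2):
            if not legal(i, j):
                continue
            run0 = 1 if eligible(i, j) else 0
            extend(
                [(i, j)],
                pair_energies[pair_type(seq1[i], seq2[j])],
                run0,
                run0 >= seed_len,
            )
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def top_k_duplexes(all_duplexes, k):
    """k best by (energy, pairs) — chains are unique by construction."""
    return all_duplexes[:k]


# ---------------------------------------------------------------------------
# curation


def overlap_frac(a, b):
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start, b.end - b.start)


def record_match(a, b, thr):
    d = overlap_frac(a.arm1, b.arm1) >= thr and overlap_frac(a.arm2, b.arm2) >= thr
    s = overlap_frac(a.arm1, b.arm2) >= thr and overlap_frac(a.arm2, b.arm1) >= thr
    return d or s


def brute_force_trusted(tables, thr):
    """All-pairs replicate-concordance oracle with the documented greedy
    one-to-one grouping (descending score, coordinate tie-break)."""

    def key(r):
        return (
            -r.score,
            (
                r.arm1.chrom, r.arm1.start, r.arm1.end, r.arm1.strand,
                r.arm2.chrom, r.arm2.start, r.arm2.end, r.arm2.strand,
            ),
            r.record_id,
        )

    if len(tables) == 1:
        return [((r.record_id,), r) for r in tables[0]]
    used = [set() for _ in tables]
    groups = []
    for seed_rec in sorted(tables[0], key=key):
        members = [seed_rec]
        for t in range(1, len(tables)):
            cands = [
                r
                for r in tables[t]
                if r.record_id not in used[t]
                and record_match(seed_rec, r, thr)
            ]
            if not cands:
                members = None
                break
            members.append(min(cands, key=key))
        if members is None:
            continue
        for t, m in enumerate(members):
            used[t].add(m.record_id)
        rep = min(members, key=key)
        groups.append((tuple(sorted(m.record_id for m in members)), rep))
    return groups


# ---------------------------------------------------------------------------
# occupancy


def linear_scan_hits(spans, window):
    """spans: list of (interval, origin). Overlaps on the window strand."""
    hits = []
    for iv, origin in spans:
        if iv.chrom != window.chrom:
            continue
        if iv.strand not in (".", window.strand):
            continue
        if iv.start < window.end and window.start < iv.end:
            hits.append((iv, origin))
    return hits


# ---------------------------------------------------------------------------
# hand-crafted features, recomputed literally


def entropy_bits(seq, k):
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    n = len(kmers)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(kmers).values()
    )


def recompute_features(inst):
    """Feature-by-feature recomputation of the dense block of one
    instance, written independently of the feature builder."""
    ds = inst.duplexes
    assert ds
    energies = [d.energy for d in ds]
    mfe = ds[0]
    ptypes = [pair_type(inst.seq1[i], inst.seq2[j]) for i, j in mfe.pairs]
    i_lo = mfe.pairs[0][0]
    i_hi = mfe.pairs[-1][0]
    j_lo = mfe.pairs[-1][1]
    j_hi = mfe.pairs[0][1]
    gaps = 0
    best = cur = 1
    for t in range(1, len(mfe.pairs)):
        g1 = mfe.pairs[t][0] - mfe.pairs[t - 1][0] - 1
        g2 = mfe.pairs[t - 1][1] - mfe.pairs[t][1] - 1
        gaps += g1 + g2
        cur = cur + 1 if g1 == 0 and g2 == 0 else 1
        best = max(best, cur)
    emin = min(energies)
    ngc = ptypes.count("GC")
    len1 = i_hi - i_lo + 1
    len2 = j_hi - j_lo + 1
    sub1 = inst.seq1[i_lo : i_hi + 1]
    sub2 = inst.seq2[j_lo : j_hi + 1]
    u1_lo = min(min(i for i, _ in d.pairs) for d in ds)
    u1_hi = max(max(i for i, _ in d.pairs) for d in ds) + 1
    u2_lo = min(min(j for _, j in d.pairs) for d in ds)
    u2_hi = max(max(j for _, j in d.pairs) for d in ds) + 1
    usub1 = inst.seq1[u1_lo:u1_hi]
    usub2 = inst.seq2[u2_lo:u2_hi]
    core1 = inst.seq1[inst.core1[0] : inst.core1[1]]
    core2 = inst.seq2[inst.core2[0] : inst.core2[1]]

    def gc(s):
        return sum(c in "GC" for c in s) / len(s)

    def comp(s, k):
        return entropy_bits(s, k) if len(s) >= k else 0.0

    feats = {
        "E_min": emin,
        "E_mean": sum(energies) / len(energies),
        "n_duplexes": len(ds),
        "bp_total": len(mfe.pairs),
        "len1": len1,
        "len2": len2,
        "len_sum": len1 + len2,
        "bp_gc": ngc,
        "bp_au": ptypes.count("AU"),
        "bp_gu": ptypes.count("GU"),
        "unpaired": gaps,
        "max_stack": best,
        "seed_length": mfe.seed[1],
        "E_per_len": emin / (len1 + len2),
        "E_per_bp": emin / len(mfe.pairs),
        "E_per_gc": emin / ngc if ngc else 0.0,
        "gc_zero": 0.0 if ngc else 1.0,
        "frac_bp_gc": ngc / len(mfe.pairs),
        "frac_bp_au": ptypes.count("AU") / len(mfe.pairs),
        "frac_bp_gu": ptypes.count("GU") / len(mfe.pairs),
        "gc_union1": gc(usub1),
        "gc_union2": gc(usub2),
        "len_union1": u1_hi - u1_lo,
        "len_union2": u2_hi - u2_lo,
        "gc_joint": gc(sub1 + sub2),
        "gc_union_joint": gc(usub1 + usub2),
    }
    for name, s in (("1", sub1), ("2", sub2)):
        feats[f"gc_{name}"] = gc(s)
        feats[f"complexity1_{name}"] = comp(s, 1)
        feats[f"complexity2_{name}"] = comp(s, 2)
        for nt in "ACGU":
            feats[f"frac_{nt}_{name}"] = s.count(nt) / len(s)
    for name, s in (("core1", core1), ("core2", core2)):
        feats[f"gc_{name}"] = gc(s)
        feats[f"complexity1_{name}"] = comp(s, 1)
        feats[f"complexity2_{name}"] = comp(s, 2)
        feats[f"len_{name}"] = len(s)
    return feats
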