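# Methods

## Problem and model

An RRI site is a pair of short genomic subsequences reported as
interacting, either by a direct-duplex-detection experiment processed
through a chimeric-read pipeline or by an *in silico* screen. Such lists
carry many false positives, and ranking by predicted hybridization
stability alone does not separate functional from spurious sites. The
package learns that separation from replicated interactome data: curated
positive sites and context-local negatives are described by interaction,
sequence and graph features, and a tree-ensemble classifier is selected
on those features.

## Curation

Replicate concordance is an overlap test: records match when both arm
pairs overlap at ≥ `overlap_threshold` (default 0.30) of the *shorter*
arm, with the arm1/arm2 pairing also tested swapped. The
shorter-relative definition is deliberately lenient because boundary
accuracy differs between protocols. Grouping across replicates is greedy
one-to-one in descending score with a full coordinate tie-break, so
results are deterministic and each input record supports at most one
trusted site; the representative is the best-scoring member and the
score filter (`score_min_trusted`, default 1.0) is applied after
concordance. Whether mutual-best matching should replace greedy grouping
is an open design point; greedy was chosen for determinism and
linear-time behaviour per group, and the all-pairs oracle in the test
suite pins its semantics.

## Occupancy

Both arms of every input interaction at score ≥ `score_min_occupied`
(default 0.5 — deliberately more permissive than the trusted cutoff, a
conservative definition of "occupied") plus user-supplied
protein-binding intervals are indexed per chromosome and strand.
Single-nucleotide crosslink positions are widened by
`crosslink_flank` = 5 nt on each side. Stranded spans occupy their own
strand; strand-agnostic inputs (BED3, crosslink tracks) occupy both —
the conservative reading. When a site's positive instance is built, the
site's own arms (all replicate members of its group) are excluded from
the mask; the negative instance rebuilds its mask without any exclusion
— the site's own arms, jittered extents included, count as occupied —
and masks the cores on top. In eval mode, where only coordinates are
known, occupied interaction spans overlapping a putative arm at ≥ the
concordance threshold (of the shorter span) are treated as the site's
own detections and excluded, so a site drawn from the same interactome
as the occupancy library is never masked by itself.

## Duplex prediction

Arms are extended by `context_len` = 150 nt. Within the two windows the
engine searches antiparallel chains of legal pairs (GC/AU/GU, ambiguity
codes never pair) with per-side gaps ≤ `max_loop` = 3 nt between
consecutive pairs, scored additively: pair energies GC −2.0, AU −1.0,
GU −0.5 (arbitrary units) plus `loop_penalty` per unpaired enclosed
nucleotide. Every reported duplex must contain a seed of
`seed_len` = 5 consecutive pairs lying inside both site cores (positive
instances) or entirely outside them (negatives), and may not place any
pair on an occupied position, while the duplex as a whole may run out of
the core into the context.

The `loop_penalty` default is 3.0 — larger in magnitude than any single
pair energy. This is essential to the model's realism: with a small
per-nucleotide penalty, a gapped step through *random* sequence is
almost always profitable (some legal pair exists within the
`max_loop` × `max_loop` box ahead), so optimal "duplexes" become
window-spanning staircases whose energy measures window length rather
than complementarity; stability would then separate positive from
negative instances purely through masking geometry. With the penalty
above the largest pair gain, extension must be paid for by genuine
complementary continuation and optima are compact, seed-anchored
helices — qualitatively matching a nearest-neighbor model with interior
loop costs. A user who wants to study the permissive regime can set any
penalty in `Config`.

The search is exact, not heuristic. A backward dynamic program over pair
states augmented with the running seed length (capped at `seed_len`) and
a seeded flag yields, for every state, the exact best completion energy;
termination is allowed only from seeded states. Best-first enumeration
over path prefixes with that bound as the (exact) remaining-cost
estimate then emits duplexes in nondecreasing energy. Ties are broken by
the lexicographically smallest pair list, i.e. by the lower (i, then j)
of the first pair, making output fully deterministic. Distinctness of
suboptimals is distinctness of base-pair sets; overlap is allowed. Up to
`n_suboptimals` = 5 duplexes are returned; zero duplexes marks the
instance NA. Enumeration is capped at 2·10⁶ heap pops as a safety valve
against adversarial all-complementary inputs; the cap is unreachable on
genomic-like sequence.

An adapter can replace the internal engine with an external
thermodynamic predictor (command template + CSV/hybrid-dot-bracket
output contract). Adapter duplexes are re-validated against the same
structural constraints; accessibility-style features are only meaningful
through this route and are otherwise omitted.

## Negatives

The negative instance of a site reuses its windows, rebuilds the
occupancy mask without the own-arm exclusion, adds the two cores, and
requires pairs (not merely seeds) to stay off the cores. Negatives are therefore context-local — compositionally
similar to their positives — yet genomically disjoint from every trusted
arm and every occupied span by construction. A site whose masked context
admits no duplex contributes no negative (logged).

## Features

Each instance with ≥ 1 duplex yields one dense named vector: min/mean
energy and duplex count over the suboptimal set; pair counts and
fractions (GC/AU/GU), side lengths, enclosed unpaired count, longest
stack and observed seed length of the minimum-energy duplex; energy
normalised by summed length, pair count and GC-pair count (guarded, with
an indicator, when no GC pair exists); per-side GC content, A/C/G/U
fractions and k-mer entropies (k = 1, 2) of the duplex-covered
subsequences; the same composition over the hull of all suboptimals and
pooled across both sides (pooling halves the variance of the
composition estimate for short duplexes); and per-side core GC,
entropies and length. Sequences shorter than k yield entropy 0 by
convention.

The optional graph block merges all suboptimal duplexes of an instance
into one labelled graph (nucleotide-labelled backbone nodes, backbone
edges, one base-pair edge per distinct pair) and extracts
neighborhood-pair features: for every node pair at shortest-path
distance d ≤ `graph_distance` (4) and radius r ≤ `graph_radius` (2), the
order-independent pair of Weisfeiler–Lehman labels (r refinement rounds,
edge labels included) is hashed with (r, d) into 2^`hash_bits` (16)
counters, L2-normalised per graph. The hash is a fixed-seed blake2b, so
vectors are identical across processes and platforms. Exact defaults for
radius/distance/bits in this feature family vary between
implementations; these were fixed once and exposed in `Config`.

## Model selection and evaluation

A 200-tree random forest (fixed seed) supplies importance scores;
features below `importance_cutoff` = 1e-4 are dropped, and of the
survivors at most 256 (highest importance) are retained — the cap only
bites on the wide hashed graph block and bounds single-CPU search cost.
The randomized search draws `search_iters` = 50 configurations across
two families — histogram gradient boosting (learning rate 0.02–0.5,
30–120 iterations, ≤ 31 leaves, 32 histogram bins, patience-based early
stopping) and random forests (100–300 trees, depth and leaf-size
ranges, feature subsampling) — each scored by mean F1 on the positive
class over stratified `cv_folds` = 5 folds. Folds are *site-grouped*:
the positive and negative instances of one trusted site always share a
fold, so a model is never validated on the flank of a site it trained
on (the conservative choice; instance-level folds leak local sequence).
Class imbalance is handled by class weighting (default on). The winner
is refit on all data and one extra CV pass records per-fold F1,
precision, recall and AUC-PR. A wall-clock `time_budget` can bound the
search instead of the draw count; the default is iteration-bounded for
reproducibility. Search ranges were sized once for few-hundred-instance
training sets and are not data-dependent.

AUC-PR uses step-wise (right-continuous) integration — the
average-precision estimator — because trapezoidal interpolation is
optimistic on PR curves; the chance baseline is the positive prevalence.
The energy-only baseline scores each instance by its negated minimum
duplex energy. Mixed models concatenate feature tables row-wise over the
intersection of dense columns (graph blocks must share hash width) with
a provenance column. Persistence is a single joblib archive of the
fitted estimator plus JSON metadata (feature names, config fingerprint,
CV report); evaluation refuses tables whose feature names or config
fingerprint mismatch unless forced, and emits NA for sites without any
valid duplex.

## Synthetic fixtures

The generator emulates a replicated interactome experiment, not reads:
an i.i.d. random genome (GC 0.5); planted site pairs written into the
genome as reverse-complementary segments (length 20–40 nt) mutated at
10% per position; three replicate tables re-reporting every pair with
independent ±5 nt boundary jitter and scores drawn U(1, 8); and decoy
rows — random arm pairs at replicate-inconsistent positions with scores
U(0.05, 0.9) — emulating spurious chimeras. Planted sites are laid out
in disjoint slots wide enough that extended windows never overlap
another site. Planted cores are GC-rich (0.65) against the 0.5
background, reflecting the stacking-stability bias of real duplex-forming
regions. The default study fixture is 2 chromosomes × 100 kb with 150
planted pairs.

The *energy-matched* variant additionally plants, in the flanking
context of every site, a complementary decoy segment pair drawn at GC
0.45 whose optimal duplex energy is matched to the site's own by
rejection sampling on the internal energy model (mutations are added
until the energies cross, keeping the closest). Negative instances then
carry the same stability distribution as positives — a stability-only
classifier is uninformative by construction — while composition,
length and complexity features still differ. On this variant the
energy baseline's AUC-PR sits at the class prevalence while the full
model reaches ≈ 0.92, the qualitative point that energy alone does not
identify functional sites.

What the fixtures do *not* emulate: transcript annotation and splicing,
read-level noise and the upstream scoring model, accessibility
(intramolecular structure), shared repeat families between sites, and
real interactome class imbalance. Passing tests therefore demonstrate
that the pipeline recovers planted signal under controlled conditions
and that its components are exact/deterministic — not field performance
on real interactomes.

## Numerical and degenerate-input conventions

All energies are dyadic rationals under the default parameters, so
energy comparisons and recomputation checks are exact to 1e-9 without
tolerance tuning. Intervals are 0-based half-open internally;
interaction tables are declared 1-based inclusive and converted at the
IO boundary; output identifiers are 1-based inclusive. Minus-strand
windows are handled in strand-oriented local coordinates (masks
reversed). Empty windows, all-masked cores, seedless instances and
single-class label vectors all fail soft (empty result, NA flag, or a
named error) rather than crashing mid-pipeline. Problem sizes used in
the shipped study runs — 150-site fixtures, 40-site holdouts, 50 search
draws — are the package's default experimental scale; all are plain
`Config`/generator arguments.

## Known limitations

The additive energy model ignores stacking context and accessibility;
thermodynamic fidelity is delegated to the external-predictor adapter.
Curation is greedy, not globally optimal, under heavy boundary noise.
The NA convention (no valid duplex → no classification) means recall is
undefined over NA sites. Models are organism- and protocol-specific to
the degree their training data are; the mixed-model path mitigates but
does not remove this.
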