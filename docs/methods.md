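# Methods

## Model and procedure

`discngram` treats a protein sequence as a bag of overlapping n-grams
(windows of n residues; a length-k sequence yields k − n + 1 of them) and
asks which n-grams separate one class of sequences from the rest. The
approach is alignment-free: no positional model, no PSSM, no gap handling —
only occurrence counting, similarity pooling and a ratio statistic.

**Occurrence counting.** Every sliding-window hit counts individually, not
per-sequence presence. This is the natural reading of a frequency-based
discriminative statistic and makes the conservation identity exact: the
total count in class c equals Σ max(0, kᵢ − n + 1) over that class's
sequences.

**Similarity pooling (SF1).** Two same-size n-grams are similar when they
differ at exactly one position and the differing residue pair scores ≥ 1 in
BLOSUM62 (positively selected point mutations; at 4–8 residues the chance
of two independent positive mutations in one window is negligible, hence
Hamming distance 1). Pooling is *seed-centric*: every gram present in the
data is the seed of its own group containing its similar neighbors that are
also present in the data (never all 20·n theoretical variants). Groups may
overlap and are never merged transitively — transitive closure would chain
A↔B↔C even when A and C are dissimilar and blur the class signal. Group
membership is symmetric because the matrix is. Neighbor search buckets
grams by the n strings obtained by deleting one position; grams sharing a
bucket differ only there, giving O(total grams · n) search instead of the
quadratic all-pairs scan (which survives as the test oracle).

**Dampening.** Unbalanced class sets make raw counts incomparable, so each
gram's (pooled) counts are scaled by ln(|C| / (k − 0.1)), k = number of
classes where the gram's *raw* count is positive. Raw presence is used
deliberately: pooling already transfers counts between classes, and letting
it also widen presence would dampen twice for one phenomenon
(`dampen(profile, enriched)` always takes presence from `profile`). The
−0.1 adjustment exists so a gram present in all classes keeps a positive
weight (ln 1 = 0 would delete it); it is applied uniformly for every k, not
only at k = |C|, which preserves strict monotonicity in k and avoids a
jump between k = |C| − 1 and k = |C|. Per-class sequence counts are *not*
used for normalization — even balanced collections have very different
natural n-gram abundances.

**Discriminative ratio and selection.** With dampened weights sorted
descending (w₁ ≥ w₂ ≥ w₃), DR = w₁ / mean(w₂, w₃) with three degenerate
rules applied in order: (a) w₂ = w₃ = 0 → mean 1 (avoids division by
zero); (b) only w₃ = 0 → mean = w₂; (c) any resulting mean strictly
between 0 and 1 → mean 1 (sub-unit means would inflate the ratio). Rule
(c) also caps the outcome of rule (b). A gram is discriminative for its
top class when DR ≥ T; the comparison is inclusive. When a combined gram
qualifies, every constituent is emitted as discriminative with the combined
DR — the group, not the exact string, carries the signal. A gram can be
discriminative in at most one class: duplicates keep the occurrence with
the highest DR (ties → lexicographically smaller class label, for
determinism). Ties for the top weight make a gram non-discriminative; a
tied "highest" class is not a class-specific signal. The statistic needs a
second *and* third runner-up, so datasets with fewer than three classes are
rejected rather than silently redefining the ratio.

**Post-processing.** Discriminative 4- to 8-grams are pooled per class
(after cross-class dedup), grams that are substrings of longer survivors
are dropped (sort: alphabetical, then size — idempotent, never removes a
maximal string), survivors are mapped to every occurrence in the class's
own sequences (1-based inclusive coordinates), and hits x, y merge when
end(x) ≥ start(y) − 1, i.e. overlap or exact adjacency. The sweep runs to a
fixed point, so chains like [1,5][5,9][10,14] merge transitively to [1,14];
equal starts are ordered by descending end so the longest hit anchors the
merge. Merged output intervals always leave gaps of at least two positions.
Masking keeps residues under motifs and flips everything else to 'X',
preserving length and coordinates; overlapping motifs are a hard error
(merge first).

**Pattern dialects.** NLSdb patterns are regex-like with a lowercase `x`
wildcard (`x{a,b}` → `.{a,b}`); PROSITE patterns are dash-separated
elements with `x(a)`/`x(a,b)` repeats, `[..]` classes, `{..}` exclusions
and `<`/`>` anchors. Both convert deterministically to standard regex;
unknown tokens raise with the token and offset rather than guessing.
Matching is unanchored (unless the pattern anchors itself), case-sensitive
uppercase, spans 1-based inclusive. In masked sequences 'X' is an ordinary
character: a `.` wildcard may legitimately land in a masked gap, since the
wildcard positions of a pattern need not be discriminative. The
`wildcard_matches_mask=False` switch rewrites `.` to `[^X]` for the
stricter reading. Coverage is any-match: the fraction of subjects matched
by at least one pattern (per-pattern counts are reported separately).

**Evaluation.** The confusion matrix has rows = class in whose sequences a
gram occurs, columns = assigned class; this orientation makes the standard
identities hold verbatim (diagonal = TP, row sum − TP = FN, column sum −
TP = FP, remainder = TN). Increments are presence-based: one count per
(gram, occurring class), regardless of how often the gram occurs there. A
gram that occurs nowhere is tallied separately and folded into its class's
FN. Zero-denominator rates are reported as missing (None/NA), never
coerced to 0. ROC curves sweep the selection threshold; each threshold
yields one (FPR, TPR) point per class and the AUC is the trapezoid over the
sorted points plus the (0,0) and (1,1) anchors.

## Synthetic data: what it emulates and what it does not

The generator draws i.i.d. background residues (uniform by default — the
most sensitive setting for exercising the scoring function itself; a
Swiss-Prot-like `"natural"` composition preset is available), plants
class-exclusive motifs into a configurable fraction of each class's
sequences at non-overlapping random positions, and mutates each planted
instance with probability `mutation_rate` at exactly one position drawn
from the BLOSUM62-positive partners of the original residue — the same
single-substitution structure the combining step is designed to absorb.
Class exclusivity is enforced by rejection sampling (regenerate from a
derived seed if a canonical motif appears in another class's background),
so ground truth is unambiguous. Everything is deterministic given the seed.

What it does not emulate: domain architecture, repeat families, local
compositional bias, homology between classes, or length/abundance
correlations of real proteomes. Passing recovery tests therefore shows the
scoring function does what it claims on its own assumptions, not that
motifs recovered from real data are biologically meaningful.

Recovery scoring: a planted motif counts as recalled when at least one
discriminative item of the correct class overlaps one of its planted
intervals; an item is background when none of its occurrences (in its
assigned class) overlaps any planted interval — including items with no
occurrence in their assigned class at all, which are spurious by
construction.

A consequence worth knowing: with a uniform 20-letter background and a few
hundred length-300 sequences, the 4-gram space (160 000 strings) is dense
enough that many background 4-grams repeat within a single class by chance
and clear DR = 5 after dampening, and constituent emission propagates
qualifying groups to their whole neighborhoods. Background discovery rates
at n = 4 are therefore intrinsically high at this scale (tens of percent),
for the method as specified, while recall of genuinely planted motifs is
essentially perfect. Longer n-grams are immune (20⁶ ≫ corpus size).

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| n-gram sizes | 4–8 | below 4 the space is too small to discriminate; above 8 the distinct-gram count approaches the corpus size and runtime grows steeply (overridable with a warning) |
| selection threshold T | 5.0 | minimum DR; typical sweeps use 5–10 |
| BLOSUM62 threshold | 1 | minimum score for a residue pair to count as similar ("positive") |
| substitution | on (SF1) | off = SF2, no combining |
| residue policy | drop | records with B/Z/X/U/O/* are dropped with a warning (or rejected); ambiguity codes have no substitution scores and would poison windows |
| min length | none | optional filter; short sequences simply yield fewer windows |
| generator defaults | 5 classes, 30/50/80/120/200 × 300 aa, 2 motifs/class, plant 0.6, mutation 0.3 | the package's standard study conditions used by `scripts/acceptance.py` |

## Numerical choices and degenerate inputs

Scoring is pure-Python float arithmetic in a fixed order (count × factor,
then the ratio), so runs are bitwise reproducible and comparable against
the straight-line reference. Class order is lexicographic everywhere,
making profiles independent of input order. Output tables are sorted by
(class, DR desc, gram); DR is serialized with `repr` for lossless
round-trips. Empty FASTA, empty classes, duplicate sequence ids, unknown
labels, out-of-bounds or overlapping intervals and sub-3-class datasets are
hard errors with named offenders.

## Scaling

Profiling is O(c · n · M · l) over c classes of M sequences (longest l);
neighbor search is O(n · N) over N distinct grams via hashed
deleted-position buckets. The standard synthetic conditions (≈ 144 000
residues, ≈ 650 000 distinct grams over sizes 4–8) run end-to-end in about
a minute on one core; the test suite's oracle comparisons use 100 toy
datasets (3–5 classes, ≤ 20 sequences of ≤ 50 residues, sizes 4–5) to keep
the quadratic reference fast.

## Known limitations

Only Hamming-distance-1 similarity (no multi-mismatch pooling); no PAM or
other matrices wired in, though any symmetric 20×20 integer matrix can be
passed wherever a `SubstitutionMatrix` is accepted; no gapped motifs,
PWMs, or alignment-based refinement; PROSITE support covers the pattern
dialect, not profiles/PSSMs; the two-class case is rejected by design; and
the high background discovery rate of short n-grams at small corpus sizes
described above.
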