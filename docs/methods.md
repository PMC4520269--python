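# Methods

This note documents the models, conventions, and numerical choices behind
`svclique`: what is computed, under which assumptions, and what the
synthetic test bed does and does not demonstrate about real data.

## Scope and coordinate model

The package handles insertions and deletions of at least 20 bp.  Smaller
indels are the territory of ordinary small-variant pipelines and are
parsed but excluded from merging and evaluation by default (`min_size=0`
retains them).  Events above 50 kb are retained in merging and reported in
a separate `>50000` bucket; the canonical five-class reporting ladder
(20–49, 50–99, 100–249, 250–999, 1000–50000 bp) reflects the size range
over which short-read callers differ most.

All coordinates are 1-based and inclusive.  Every event is reduced to one
canonical anchor: the insertion position for insertions, and the *center
point* `(left + right) // 2` for deletions.  A center point plus a length
uniquely determines a deletion.  For even spans the floor makes the center
deterministic and integral; nothing downstream depends on the half-base
direction of that rounding.  On VCF input/output the standard convention
applies: POS is the base before the event, the deleted span is
`POS+1 .. END`, and SVLEN is signed (negative deletions) on output while
only its magnitude is trusted on input, because callers disagree about the
sign.

## Compatibility criteria, not reciprocal overlap

Two calls are *compatible* — candidates for describing the same event —
when they share chromosome and type, their anchors are within
`max_breakpoint_distance` (L) bp, and their lengths differ by at most
`max_length_deviation` (T) bp.  Defaults are (50, 20).  Per-tool criteria
reflect breakpoint accuracy of the calling technique: split-read callers
(base-accurate) get (20, 10), internal-segment callers (insert-size
statistics, fuzzy breakpoints) get (100, 100), hybrids (50, 20).  A pair
of calls from different tool classes is judged by the element-wise
maximum, i.e. the more permissive limit of each pair.

Reciprocal overlap is implemented only as a documented counter-example
(`max_offset_for_reciprocal_overlap`): at 50% reciprocal overlap two
10 kb deletions may disagree by 5000 bp in breakpoint position while two
20 bp deletions may disagree by only 10 bp.  The tolerance thus scales
with event size rather than with any caller's actual breakpoint error,
and no overlap notion exists for insertions, so overlap-based matching is
used neither for merging nor for evaluation.

## The collision null model

For call sets of sizes K1 and K2 placed uniformly at random on a genome
of length G, with a per-pair collision window of L bp, the probability
that at least one cross-set pair collides is

    P(K1, K2, G, L) = 1 − (1 − L/G)^(K1·K2) ≈ 1 − exp(−K1·K2·L/G).

The exact form is evaluated in log space (`log1p`/`expm1`) so it neither
underflows nor loses precision for large K1·K2; the exponential
approximation agrees with it to well under 1e−3 whenever K1·K2·L/G ≤ 0.1
and L/G ≤ 1e−4.  `calibrate_distance_threshold` inverts the exact form,
returning the largest integer L with P(L) ≤ α (verified to bracket:
P(L) ≤ α < P(L+1)).

**Window convention.**  The formula charges each of the K1·K2 pairs a
collision probability of L/G, so L is the *total width* of the collision
window.  A symmetric distance criterion |a−b| ≤ D admits 2D+1 integer
offsets; `collision_window(D) = 2D+1` is the window that makes the closed
form agree with placement simulations of the criterion
(`empirical_collision_probability` confirms agreement within Monte-Carlo
error across call-set sizes and genome lengths).  The rule-of-thumb check
"P at a 50 bp window stays below 0.01" is meaningful for call sets that
actually satisfy the null model's premise of uniform placement — in the
synthetic suite, the false-positive layers (e.g. K1 = K2 = 10 planted FPs
on 2 Mb gives P ≈ 0.0025).  True-positive calls cluster on real events by
construction, so applying the null model to them answers no useful
question at any genome size.

## Merging algorithm

Calls from all tools form a *call graph*: nodes are calls, edges connect
compatible pairs (including same-tool pairs by default, which unifies one
tool's duplicate or fragmented calls; `allow_same_tool=False` restricts to
cross-tool edges).  Construction sorts calls by (chrom, anchor) and sweeps
a window of the widest applicable distance threshold, giving near-linear
behaviour at realistic call densities; a quadratic all-pairs oracle checks
its output in the tests.

Maximal cliques — sets of pairwise-compatible calls to which nothing can
be added — are enumerated with Bron–Kerbosch with pivoting.  Correctness,
not the algorithm, is the contract: the enumerator is tested against
exhaustive subset enumeration and against an independent library
implementation.  Output order is deterministic (leftmost member, then
member ids).

Each clique collapses to one consensus call.  The consensus anchor and
length come from the member whose tool has the best (lowest) accuracy rank
— split-read before hybrid before internal-segment by default — because
those tools' breakpoints are the most trustworthy; among equal-rank
members the lower median is taken (breakpoint and length independently).
A call with no length estimate satisfies length criteria vacuously but
never supplies the consensus length.  Overlapping maximal cliques are
resolved by the default `greedy_disjoint` policy: cliques are processed
largest-first (ties leftmost-first), consumed calls are removed, and empty
cliques are suppressed, so each call contributes to exactly one output
call and the merged set forms a single non-redundant track.  The
`all_cliques` policy preserves the raw clique structure for analysis.

Design points that were genuinely open and decided here: the consensus
*length* rule extends the accuracy-rank rule (only the breakpoint rule is
forced by the accuracy argument); consensus coordinates are the
representative member's own, not an average; and `greedy_disjoint` is the
default because a merged output should assign each input call one
interpretation.

## Benchmarking

Matching predictions to truth reuses the compatibility geometry, with
regimes `strict` (50, 20) and `relaxed` (100, 100).  Each prediction links
to at most one truth event — nearest center, ties by smaller length
difference then truth id — while several predictions may spot the same
truth.  This realizes the asymmetric definitions without double counting:
precision = % of predictions matching truth, recall = % of truth spotted,
F = 2pr/(p+r).  Unmatched DEL (INS) predictions are *rescued* by a mixed
substitution event when its signed effective length (del_len − ins_len,
positive = net deletion) matches the predicted length within the regime's
length threshold; rescues feed the `Mix.` percentage (denominator: all
predictions in the class — the defensible alternative, unmatched
predictions only, would make the column incomparable with precision) and
never count toward precision.

Stratification assigns matched pairs to the class of the TRUTH length
(keeping recall denominators equal to truth-set counts) and unmatched
predictions to their own length's class.  Empty denominators are NA in
tables and 0 at radar vertices, because pentagons need numbers; both
representations are emitted.  Radar vectors are the tabular values
rescaled to [0, 1], one vertex per canonical class.

## Synthetic data

The generator produces, deterministically per seed: an i.i.d. reference
(default GC 0.36, plant-like); a non-overlapping truth set with exact
per-class, per-type counts, uniform positions subject to a minimum gap,
and uniform lengths within each class; a donor genome with events applied
left-to-right under cumulative offset tracking (validated by a liftover
round trip and flank-identity checks); and virtual-tool call sets with
Gaussian integer-rounded breakpoint/length jitter (roughly symmetric
error is what average center-distance reporting implies), per-class
detection probabilities, and Poisson false positives with log-uniform
lengths on [20, 50000].  Events are placed largest-footprint-first, since
scattering hundreds of small events first would fragment the free space
and starve multi-kb deletions.  The default minimum gap is twice the
largest requested class bound, which makes truth matching unambiguous;
dense scenarios override it explicitly.

The standard study (`benchmark_scenario`) fixes the conditions used by
the end-to-end tests: 2 chromosomes × 1 Mb; ~600 events skewed toward
small classes as validated SV sets are (DEL 150/100/80/40/10,
INS 120/60/30/8/2 across the ladder, plus 10 mixed events); four virtual
tools — two split-read-like (jitter sd 3/5 bp, per-class detection
0.95/0.90/0.85/0.80/0.70) and two internal-segment-like (sd 25/40 bp,
detection 0.60/0.70/0.85/0.90/0.95) — each with 5 false positives per Mb.
The problem size keeps every end-to-end test within seconds while leaving
each size class populated.

What passing these tests shows: the geometry, the clique machinery, the
consensus rules, and the metric bookkeeping are correct, and the
false-merge rate behaves as the null model predicts for independently
placed calls.  What they do not show: behaviour under correlated caller
errors (real tools fail on the same repetitive loci, violating the
independence assumption), heavy-tailed breakpoint errors, read-level
artifacts, or ploidy — none of which the call-level noise model emulates.

One comparison deserves its note: "merged recall within 2 points of
pooled recall per class" is evaluated under the relaxed regime.  Under
strict matching the comparison is dominated by the IS tools' length noise
(sd 40 bp against a 20 bp threshold): pooled scoring takes a best-of-k
match over redundant calls while the consensus takes a single lower-median
draw, so a few points of apparent "loss" appear in classes detected only
by IS tools — a property of the noise model, not of the merging.  The
relaxed thresholds cover the IS tools' own stated error magnitudes, making
the comparison measure merging fidelity.  (With jitter bounded inside the
strict thresholds, merging provably loses no spotted truth, and the suite
asserts exactly that.)

## Numerical and degenerate-input choices

* Probabilities: log-space exact form; P = 0 when L = 0 or K1·K2 = 0;
  domain errors for G < 1 or L > G.
* Calibration nudges the analytically inverted window by at most one step
  to absorb float rounding against the exact boundary.
* Ties everywhere break on ids after coordinates, so every output is
  permutation-invariant and byte-reproducible.
* Empty call sets produce header-only VCFs and NA-filled report rows;
  evaluation with an empty truth set is a configuration error.
* VCF records that cannot yield a positive length are skipped, counted,
  and logged — never fatal.

## Limitations

Inversions, translocations, duplications, and breakend notation are out
of scope, as are genotype-aware merging and read-level simulation.  The
null model assumes independent uniform call placement; real false calls
cluster in repetitive sequence, so the calibrated thresholds are a floor,
not a guarantee, on real genomes.
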