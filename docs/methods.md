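# Methods

## Problem and model

An optical restriction map (ORM) of a genome is an ordered list of fragment
sizes `o_1..o_m` (bp) produced by a restriction enzyme with a short
recognition site. A contig digested in silico with the same enzyme yields
its own ordered sizes `c_1..c_n`. If the contig truly occupies a contiguous
stretch of the genome and both digests were perfect, `c_1..c_n` would equal
a contiguous slice of `o_1..o_m`. Real digests are not perfect: restriction
sites are missed (adjacent fragments merge) and fragment sizes carry
measurement or sequencing error. The scorer therefore searches for the best
*grouped* correspondence, and the placement step resolves competition
between contigs for map intervals.

## Greedy scoring

For a fixed start fragment `o_i`, the scorer maintains one open group per
side: a contig group sum `cs` and a map group sum `og`. Starting from
`cs = c_1`, `og = o_i` it repeats:

* if `|cs − og| ≤ tol`: record a matched site, add `|cs − og|` to the
  running size-difference total, and open fresh single-fragment groups on
  both sides;
* else if `cs < og − tol`: append the next contig fragment to the contig
  group (a missed site in the map's favour);
* else: append the next map fragment to the map group (a missed site in the
  contig's favour).

Every non-matching advance increments the missed-site count `MRS`, and the
final score is `Σ |group differences| + P·MRS`. The first index at which the
sums agree terminates a group (least-prefix rule), and the tolerance test
uses the closed interval.

**Group tolerance.** `tol` is the sum of the per-fragment tolerances
`σ_j` of the map fragments currently in the group (reset when a group
closes). Per-fragment sizing errors accumulate across a merged group, so a
group spanning k fragments must be allowed the combined uncertainty of its
parts; bounding each fragment's error by `σ_j` makes the sum the exact
worst-case group bound for bounded multiplicative noise. With a constant σ
and no merging this reduces to plain "sums agree up to σ". Using instead a
single per-position σ for arbitrarily large groups makes recovery collapse
(to ~50% accuracy at the mildest error level we simulate) because one
over-tolerance fragment triggers a cascade of penalised merges; the
accumulated form restores the graceful degradation a size-tolerant matcher
is meant to have.

**Edge rules at the right end of the map.** When the contig extends past
`o_m`, its remaining fragments are folded into the final group matched at
`o_m`, one missed site per folded fragment, and the group difference is
recomputed. When the contig is exhausted while a group is still open, the
group is closed as a match against the current map fragment (its full size
difference is charged, no extra miss, since no advance occurred). These
rules make every mapping well-defined for every start `1 ≤ i ≤ m`,
including `i = m`, where the last contig fragment always lands on `o_m`.

**Parameters.**

* `P` (penalty per missed site, default 999): must dwarf typical group size
  differences so that structural disagreement dominates sizing noise. Lower
  values suit noisier data.
* `σ` / per-fragment `stds` (bp, default 0): either a global tolerance or a
  per-fragment vector carried by the map. The simulator's default ties
  `σ_j = resize_pct/100 · o_j` to the injected noise (see below).

Scores are exact integers whenever fragment sizes and `P` are integers: the
tolerance only affects *which* groups form, never the integer arithmetic of
the score itself. The inner walk is JIT-compiled with numba; the identical
source function runs under plain Python when numba is absent.

**Complexity.** Each walk consumes contig fragments monotonically and
advances the map pointer only while the map group sum trails the contig
group sum, so a start costs O(n) amortised for size distributions without
extreme outliers, and the full table O(m·n·r). An adversarial contig (one
giant fragment) can force an O(m) walk for a single start; this does not
arise in restriction digests of genomic sequence.

## Placement

All three algorithms sort each contig's m mappings by ascending score
(stable, so equal scores stay in ascending start order) into `L_C`.

* GPA1 processes contigs by the start fragment of their best mapping,
  ascending, one attempt each.
* GPA2 processes contigs by `b_C = max` matched sites over all mappings,
  descending — contigs with more corroborating sites are anchored first.
* GPA3 processes contigs by best score, ascending.

GPA2/GPA3 try up to `d` entries of `L_C` (default `d = 5`, configurable; a
small retry budget, since entries past the first few have large scores and
little support). Overlap is tested on closed fragment-index intervals and a
shared boundary fragment counts as overlap: one map fragment belongs to at
most one contig. Every sort is stable with ties broken by ascending contig
input index; if several mappings tie for a contig's best score the smallest
start wins. Fixed inputs therefore give bit-identical scaffolds.

In our simulations GPA2 is usually the most error-robust and GPA3 the most
aggressive (it places low-scoring contigs first, which under heavy error
lets confidently-wrong mappings pre-empt true ones, raising wrong
placements). All three coincide at 100% recovery on error-free input.

## Synthetic data generator

The generator emulates the standard evaluation protocol for map-based
scaffolders, at genome scales where a laptop run takes seconds:

* **Genome**: iid uniform bases, default lengths 10⁵–10⁶ bp. A uniform
  4-mer site (default `GATC`) then cuts on average every 256 bp, giving
  maps of a few thousand fragments — the same fragment-count regime as a
  bacterial genome mapped with a 6-cutter.
* **Fragmentation** (`snap_to_site`): contig boundaries are drawn uniformly
  from the map's internal restriction-site cut points, subject to two
  constraints. (a) The map fragment preceding a chosen cut must be at least
  the site length, so no recognition-site occurrence straddles a boundary;
  this guarantees each error-free contig digest equals an exact contiguous
  ORM slice. (b) Every contig spans at least `min_fragments` map fragments
  (default 3). The floor exists because sub-resolution contigs are
  ambiguous by construction: in a ~2,000-fragment map the sizes follow a
  near-geometric distribution and a given single fragment size recurs ~4
  times, so a one-fragment contig has several exactly-tying zero-score
  placements and no size-based method can order it. Three consecutive
  fragment sizes are, with overwhelming probability, unique. Constrained
  sampling uses the standard gap transform (uniform over all admissible
  breakpoint sets) with rejection only for constraint (a).
  An `arbitrary` mode cuts at uniform base positions instead, producing
  truncated boundary fragments, for realism studies.
* **Permutation**: contig order is shuffled; truth records each contig's
  ORM interval, genomic interval and rank.
* **Missed sites**: each internal digest boundary is dropped independently
  with probability `p`, merging neighbours (total bp conserved). Errors are
  injected into contig digests only, matching the view that the sequence-
  derived ORM is the trusted side; perturbing the ORM too is possible by
  scoring against a perturbed map.
* **Resize**: each fragment is scaled by `1 + u`, `u ~ U(−pct/100,
  +pct/100)`, rounded to the nearest bp with a 1 bp floor.
* **Seeds**: one master seed; genome, fragmentation/permutation, missed-site
  and resize stages each use a spawned child generator, so runs are fully
  reproducible and error channels are independent.

Default error grid: `(p, pct) ∈ {(0,0), (0.1,5), (0.2,10), (0.3,20)}` with
`r ∈ {50, 200}` contigs — mild to severe corruption. Under the defaults the
scorer's tolerance is set from the known noise (`σ_j = pct/100 · o_j`);
with real data σ must come from the mapping platform's sizing-error model.

**What the generator does not emulate.** Contigs tile the genome exactly
(no assembly gaps, overlaps, chimeras or repeats collapsed by the
assembler); contigs are always in forward orientation (an optional
`try_reverse` scoring flag handles reversed fragment lists, off by
default); the ORM itself is error-free, with no partial digestion,
desorption or chimeric molecules; and genome composition is uniform-random,
so fragment sizes are nearly geometric and repeats are absent. Passing
tests therefore demonstrate the correctness and error-response of the
matching and placement machinery, not end-to-end performance on real
optical-mapping data.

## Evaluation

A contig is counted correct iff its assigned start fragment equals its true
start fragment — the strictest checkable criterion, and the one under which
error-free recovery is exactly 100%. Discarded contigs (including GPA2/3
retry exhaustion) are conflicts; placed-but-elsewhere contigs are wrong
placements; accuracy = 100·(r − conflicts − wrong)/r.

## Numerical and design choices

* Cut position: immediately before the first base of each site occurrence;
  occurrences may overlap (scan restarts one base after each found start);
  matching is case-insensitive and `N` never matches. Only consistency
  between map and contig digests matters, not the intra-site offset.
* Degenerate inputs: empty contig lists, out-of-range starts, non-positive
  fragment sizes and malformed map files are rejected with explicit errors.
* The acceptance script runs 5 seeds × 50 contigs at 6×10⁵ and 8×10⁵ bp;
  the test suite's trend check uses 20 seeds per error level at r = 50
  (5×10⁵ bp) and r = 200 (10⁶ bp). These sizes keep full-suite runs at
  about a minute while leaving binomial noise on a 50-contig accuracy at
  ±2 percentage points per seed mean.

## Known limitations

* The scorer is greedy, not an optimal dynamic-programming map aligner: a
  locally acceptable group can pre-empt a globally better split, which is
  the price of O(m·n·r) scoring.
* Contig orientation is not searched by default (forward-only, as in the
  placement algorithms' definition).
* Placement is sequential-greedy; no backtracking or global ILP/DP
  refinement, so one early bad anchor can evict several true placements.
* Gap sizes between placed contigs are not estimated; scaffold FASTA output
  is gap-free concatenation.
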