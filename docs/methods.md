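# Methods

## The folding model

`tilefold` implements Nussinov-style maximum-base-pair folding: free energy
is proxied by the number of complementary base pairs, and the optimal
non-crossing structure of a strand x_1..x_N is found by the cubic dynamic
program

    S[i][j] = max( S[i+1][j-1] + sigma(i, j),
                   max_{i <= k < j} ( S[i][k] + S[k+1][j] ) ),

with S zero on and below the diagonal and sigma(i, j) = 1 iff (x_i, x_j)
is an allowed pair with j - i >= 2.  The "match" predicate is a modelling
choice, not part of the recurrence: the default rule is Watson-Crick
(A-U, G-C) plus the G-U wobble pair, which is standard for max-pairing
objectives; a strict Watson-Crick rule and the empty rule are available
(`PairingRule`).  The minimum separation of 2 forbids hairpin loops of
fewer than one unpaired base.  No energy model, pseudoknots or suboptimal
structures: the package's subject is the *execution schedule* of the
recurrence, and the folding layer exists so the schedules compute something
real and checkable.

Traceback is not needed for scoring and admits ties; it is made
deterministic by preferring the pairing branch when it attains the optimum
with sigma = 1, otherwise the smallest split point, recursing left-first.

An enumeration oracle (`brute_force_max_pairs`, backtracking over the
leftmost index with no memoization, capped at N = 16) is kept deliberately
independent of the DP and anchors the correctness tests.

## Statement instances and dependences

The serial loop nest executes, per upper-triangle cell (i, j), the split
updates s1(i, j, k) for k = 0..j-i-1 and then the pairing update s2(i, j);
rows run with i descending.  Every such execution is an `Instance`; its
list position in `enumerate_instances(N)` is its timestamp.

The dependence graph is built from per-cell access lists: s1(i, j, k)
reads S[i][i+k], S[i+k+1][j] and S[i][j] and writes S[i][j]; s2 reads
S[i+1][j-1] and S[i][j] and writes S[i][j]; reads of the never-written
diagonal and lower triangle are dropped.  Edges connect each access to its
most recent conflicting predecessor (at least one side a write), which
covers flow, anti and output conflicts; the transitive closure of these
consecutive-conflict edges equals the closure of all pairwise conflicts.

### Closed-form transitive closure

Reachability p -> q has a closed form that follows from the per-cell write
chains (all writers of a cell precede all foreign readers):

* same cell: p earlier in the chain (s1 by ascending k, then s2);
* iq < ip and jq >= jp: true for *every* instance of q's cell — the final
  value of p's cell propagates through cell (iq+1, jq) into the k = 0
  split read of q's cell;
* same row (ip = iq, jp < jq): the value enters q's cell only through the
  split read at k = jp - iq, so s1 targets need kq >= jp - iq (the
  trailing s2 is always reachable);
* otherwise unreachable (paths only move cells up rows and right columns).

The closed form is *defined* as exact only because the tests prove it:
equality with brute-force graph reachability (networkx) is asserted
exhaustively for every N <= 12 and on sampled pairs at N = 25.

## Tiles and slicing correction

Rectangular tiles of size b1 x b2 x b3 are laid over execution-order
coordinates: ii = (N-1-i)//b1, jj = (j-i-1)//b2, kk = k//b3.  Two
normalization choices are deliberate:

* The published constraint set for the parametric tile is typographically
  corrupted in its source, so the coordinates above are a reconstruction
  that preserves the roles of ii/jj/kk (row block in execution order,
  offset block, split block) rather than a transcription.
* s2(i, j) is assigned to the **last** k-block of its cell,
  kk = (j-i-1)//b3.  s2 closes the cell's split loop; placing it in any
  earlier block would make it depend on later tiles of its own cell.  With
  this placement the correction set for s2 is empty for *every* (N, B)
  tested — the property the method's authors report for their generated
  codes — and the corrected tiling stays a partition.

Correction applies the closure to the slicing sets, per tile id II in
lexicographic order:

    TILE_ITR(II) = TILE(II) - R+(TILE_GT(II))
    TVLD_LT(II)  = (R+(TILE_ITR(II)) cap TILE_LT(II)) - R+(TILE_GT(II))
    TILE_VLD(II) = TILE_ITR(II) cup TVLD_LT(II)

Note the direction: TVLD_LT(II) contains instances whose *original* tiles
precede II and which are dependence *targets* of TILE_ITR(II) — moved work
therefore lands in lexicographically **later** tiles, never earlier ones.

The implementation computes the same partition instance-wise:

    corrected(q) = lexmax( original(q), max over closure sources p of original(p) )

The equivalence argument: q leaves TILE_ITR(original(q)) iff some source
sits in a later tile; q then belongs to TVLD_LT(II*) for II* the tile of
its lexicographically greatest source, because (a) original(q) < II*,
(b) no source of q is beyond II*, and (c) the witness source p with
original(p) = II* is itself uncorrected — any source of p is also a source
of q by transitivity, so max_source(p) <= max_source(q) = II*.  The tests
additionally verify the identity against the literal set equations
evaluated with the brute-force closure.

`max_source_tile` is O(1) per instance: each of the three source families
(down-left cone, same row, own cell) has a componentwise-dominant
representative — the last instance of cell (i+1, j), of the largest
same-row source cell, and the chain predecessor respectively.

Two empirical regularities follow from the normalization and are verified
rather than assumed:

* With b1 = 1 no instance is ever corrected (every source then lies in a
  strictly smaller ii or an earlier same-row block).  This is the
  "pre-verified family" (1, b2, b3): the production executor runs it at any
  N without instance-level construction.  Tiling only the two inner loops
  is also the regime the method's authors single out as the profitable one.
* With b1 > 1 corrections are real (e.g. 240 moved instances at N = 20,
  B = (2,2,2)), always s1, always forward.

## Schedules

* `fill_reference` — canonical serial order; the split reduction over k is
  one vectorized max, arithmetically identical to the serial updates.
* `chang_fill` — diagonal-synchronized: cells of one diagonal d = j - i
  are mutually independent and may run concurrently; a barrier separates
  diagonals.
* `li_fill` — same diagonal order, but every finalized cell is mirrored
  into the lower triangle and the column operand of the split term is read
  through the mirror (S[j][k+1] for S[k+1][j]), making both operands
  row-contiguous.  The mirror invariant S[j][i] = S[i][j] is maintained
  and tested.
* `tiled_fill` — corrected tiles executed wavefront by wavefront,
  w = ii + jj, kk serial within a macro-tile (ii, jj); instances inside a
  tile run in serial timestamp order.

Concurrency is a *contract*, not an OS-thread implementation: `workers`
asserts independence, and a seeded `rng` can shuffle within-diagonal cell
order (baselines) or within-wavefront macro order (tiled) to let tests
check that any admissible interleaving yields the same matrix.  Every
dependence edge either stays inside a macro-tile with non-decreasing kk or
crosses to a strictly later wavefront; macro-tiles of one wavefront are
pairwise independent, checked at cell granularity (whether any instance of
one cell reaches any instance of another depends only on the two cells).

`tiled_fill` refuses what it cannot verify: tile sizes outside the b1 = 1
family require the full oracle (corrected-tiling construction, lexicographic
validation, wavefront contract), which is tractable only at desk scale
(default cap N = 150); beyond that such sizes are rejected rather than run
unvalidated.

## Parametric factor model

Generating the same tiled code for two fixed tile-size vectors yields
identical structure with different integer factors; each factor position
gives a pair (y1, y2) assumed to follow

    y = a0*(b1*b2) + a1*b1 + a2*b2 + a3*b3 + a4,

integer coefficients, at most two nonzero.  (The published form of this
equation prints a1 against both b1 and b2; the reading implemented here is
the only one consistent with every row of the published factor table, all
ten of which are regenerated and re-fitted in the tests.)  Default sizes
are the primes B1 = [23, 47, 113], B2 = [37, 79, 167]; primality keeps
products and sums from colliding, which is what makes two equations
identify a two-unknown support.

Fitting searches supports in a fixed priority order — constant; single
linear terms b1, b2, b3; the product b1*b2; linear term + constant; linear
pairs; product-involving pairs — solving each 2x2 system with integer-only
arithmetic (Cramer + divisibility).  The first rank with an exact solution
wins; several distinct solutions inside one rank raise an ambiguity error
listing the candidates (never silently chosen), and exhausting all ranks
raises an unmodellable-pair error.  The priority order is this package's
own determinism device; the original workflow defers to an external
constraint solver whose tie-breaking is unspecified.

## Tile-size selection

`tss_enumerate` takes the Cartesian product of per-dimension candidate
lists; the default list has the 20 values 1, 2, 4, 6, 8, 12, 16, 24, 32,
40, 48, 64, 96, 128, 150, 200, 256, 300, 400, 512, hence 20^3 = 8000
candidates.  `tss_search` validates each candidate (family membership, or
the full oracle at a proxy size, default N = 24 — instance-level closure at
production N is out of reach, and the proxy mirrors the per-size validity
check of the original workflow at tractable cost), then times `tiled_fill`
with one warm-up plus the median of `repeats` runs (default 3), and ranks
valid candidates by ascending runtime with the tile size as deterministic
tie-break.  The timer is injectable, so the search logic is a pure function
of its inputs and is tested with fake timers against exhaustive minima;
wall-clock numbers are hardware-bound and never used as correctness
criteria.  The qualitative expectation that good sizes have b1 = 1 and
b2 roughly tenfold b3 is reported by searches, not asserted.

## Synthetic data

`synth_rna` draws i.i.d. residues from configurable base frequencies
(default uniform) with a seeded generator — the same notion of "randomly
generated strands" the method's evaluation uses, at lengths chosen for the
test budget (pools of 200 strands at N in 2..64 plus single strands at 128
and 300; production lengths in the thousands are supported by the family
executor but not exercised in tests).  I.i.d. strands have no biological
composition bias or repeat structure; that is irrelevant for schedule
validity (which depends only on N) and for score equivalence (bit-exact for
any input), so passing tests say nothing about folding accuracy on real
transcripts — accuracy of the max-pairing objective itself is out of scope.

## Numerical and degenerate-input choices

Scores are int64 throughout; no floating point enters any result.  N = 1
folds to a 1x1 zero matrix; empty sequences are errors.  Tile sizes are
validated >= 1; B = (N, N, N) degenerates to a single tile and one
wavefront.  All randomness flows through explicit integer seeds; identical
configurations produce byte-identical output files.

## Known limitations

* Arbitrary (b1 > 1) tile sizes run only at desk scale; production scale is
  restricted to the verified (1, b2, b3) family.
* The wavefront skew is fixed to w = ii + jj and verified by the oracle;
  steeper skews are not explored.
* No C/OpenMP code generation or symbolic (parametric-N) set manipulation:
  schedules are executed in-process, and wall-clock comparisons between
  them are explicitly not reproduced.
* `workers` does not spawn OS threads; the package verifies parallel
  *validity*, not parallel *speed-up*.
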