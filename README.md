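# tilefold

Nussinov RNA folding under tiled execution schedules — for people who care
both about the fold and about how the cubic loop nest that computes it is
scheduled on a multi-core machine.

## What it computes

Nussinov's dynamic program scores a strand x_1..x_N by the maximum number
of complementary base pairs a non-crossing secondary structure can hold:

    S(i,j) = max( S(i+1,j-1) + sigma(i,j),  max_{i<=k<j} S(i,k) + S(k+1,j) )

with sigma(i,j) = 1 iff (x_i, x_j) is an allowed pair (Watson-Crick + G-U
wobble by default) and j - i >= 2.  S(0, N-1) is the optimal pair count; a
deterministic traceback yields one optimal structure in dot-bracket form.

The same matrix can be filled under several schedules, all bit-exact:

| schedule    | idea                                                        |
|-------------|-------------------------------------------------------------|
| `reference` | canonical serial order (rows bottom-up, splits before pairs) |
| `chang`     | diagonal-by-diagonal with a barrier between diagonals        |
| `li`        | diagonal order + transposed lower triangle so both split operands stream along rows |
| `tiled`     | b1 x b2 x b3 tiles corrected by iteration-space slicing, executed in wavefronts w = ii + jj |

The tiled schedule is the point of the package.  Rectangular tiles over
the triangular iteration space are not valid as-is; `tilefold` builds the
exact instance-level dependence graph, applies its transitive closure
(closed form, oracle-verified against brute-force reachability) to the
slicing sets TILE_ITR / TVLD_LT / TILE_VLD, and executes the corrected
tiles wavefront by wavefront, refusing any configuration its validity
oracle cannot confirm.  On top sit:

* a sparse integer **factor model** y = a0·b1·b2 + a1·b1 + a2·b2 + a3·b3 + a4
  (at most two nonzero coefficients) that lifts two fixed-tile-size codes
  into one parametric code by fitting factor pairs exactly, and
* **tile-size selection**: enumerate a candidate grid (default 20 values
  per dimension, 20³ = 8000 sizes), validate each candidate, time the
  tiled fill, rank by median runtime.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```
$ tilefold synth --length 60 --seed 7 --out demo.fa
wrote demo.fa (60 nt)

$ tilefold fold --fasta demo.fa --schedule tiled --b 1,8,2 --out-prefix demo
synth-n60-s7    N=60    pairs=23

$ head -2 demo.synth-n60-s7.dbn
GUUACUAUUCCCCCGGUUGUAAGAAGCUGGCAAAGACAUACUGUGGAGGUCGACCAUCUG
.(.(((.((((((.))((.(.)))(..))).)))).((((.))))(((((..))).))))
```

`pairs=23` is S(0, 59), the maximum base-pair count, here computed by the
slicing-tiled wavefront schedule with tiles of size 1 x 8 x 2; the
dot-bracket line is the traceback structure carrying exactly those 23
pairs.  Any `--schedule` choice prints the same count — that equivalence
is the package's central tested property.

Validate a tiling and inspect the correction:

```
$ tilefold validate --n 12 --b 2,3,5
INFO tilefold: N=12 B=(2, 3, 5): 352 instances, 22 corrected tiles, 25 moved instances
VALID: 0 dependence violations
```

With b1 = 2 the slicing correction is real (25 of 352 instances move to
later tiles) yet the corrected schedule has zero violations.  Tile sizes
with b1 = 1 need no correction at all; that family runs at any N.

Fit the parametric factor model from observed factor pairs:

```
$ printf 'L6\t93\t153\nL10\t70\t116\nL40\t113\t167\n' > pairs.tsv
$ tilefold fitmodel --pairs pairs.tsv --out model.tsv
fitted 3/3 factor pairs
$ cat model.tsv
label   y1      y2      a0      a1      a2      a3      a4      formula
L6      93      153     0       2       1       0       0       2*b1+b2
L10     70      116     0       1       1       0       0       b1+b2
L40     113     167     0       0       0       1       0       b3
```

The pair (93, 153), observed at the same position of two codes generated
for the prime tile sizes [23, 47, 113] and [37, 79, 167], resolves to the
expression 2·b1 + b2 — the factor the parametric code substitutes at that
position.

Tile-size selection over a small grid:

```
$ printf 'b1: [1]\nb2: [2, 4, 8]\nb3: [1, 2]\n' > grid.yaml
$ tilefold tss --synth-n 200 --grid grid.yaml --repeats 3 --out tss.csv
```

writes a table of (b1, b2, b3, valid, runtime_s, rank) rows, ranked by
median runtime.

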