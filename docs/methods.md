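# Methods

## The problem

A unique molecular identifier (UMI) is a random oligonucleotide attached to
each molecule before amplification so that PCR duplicates can be collapsed
to a single count. Substitution errors introduced during PCR and sequencing
corrupt UMIs, create spurious "new" molecules, and inflate counts — the more
PCR cycles, the worse. `trimercount` implements an error-correcting UMI
design: each UMI base is synthesized as a homotrimer block (`b -> bbb`), so
a 12-base UMI is carried as 36 bases. Within-block disagreement reveals
errors; the block's modal base corrects them.

## Majority-vote correction

For a block of three observed bases:

* unanimous (`AAA`) — no error, collapse to `A`;
* 2-of-3 (`AAT`) — one substitution, the majority restores the truth;
* all distinct (`ACT`) — two substitutions, *inconclusive*: no majority
  exists.

The per-block error count is `3 − multiplicity(modal base)` — the minimum
number of substitutions needed to return the block to unanimity (0, 1 or 2).
Summed over blocks this is the UMI's error load, used by the read filters
(default: drop reads with load > 3 before set-cover counting; the bulk
long-read path uses > 5). The metric is a deliberate design choice: it
counts base-level corruption conservatively and makes "more than three
errors" well defined at the block level. Ambiguity codes (`N`) never win a
vote; a block such as `ANN` is inconclusive rather than called `N`.

Two identical substitutions in one block (`GGG -> TTG`) out-vote the truth;
this is the method's intrinsic failure mode and is asserted explicitly in
the tests.

## Set-cover deduplication

Inconclusive blocks mean a read cannot be collapsed on its own. Reads of a
gene (and cell, in single-cell data) are then resolved jointly: for each
sequenced homotrimer UMI `s`, the candidate set `C(s)` contains every
monomer obtainable by choosing one *observed* base per block; the estimated
molecule count is the cardinality of the smallest set of monomers that
explains every read — a minimum set cover over the subsets
`S_c = {s : c ∈ C(s)}`.

* Production path: the classical greedy algorithm (largest marginal
  coverage first), with the `(ln|S| + 1)`-approximation guarantee. Ties
  break toward the lexicographically smallest candidate so results are
  deterministic.
* Oracle path: an exact minimum cover for validation — exhaustive search in
  order of increasing cardinality over bitset-encoded coverage sets
  (deduplicated by coverage, upper-bounded by the greedy solution), or an
  integer linear program solved with HiGHS (`scipy.optimize.milp`). Both
  backends are cross-checked against each other and against a brute-force
  oracle in the tests; the exact solver refuses instances above 20 distinct
  UMIs because it exists for validation, not production.

Design choices where the formulation was open:

* `C(s)` uses *all* distinct bases observed per block (a 2-of-3 block
  contributes two candidates), which follows the formal set definition; the
  majority-only fast path (count distinct majority collapses) applies only
  when every read in the group is conclusive.
* Coverage is evaluated over distinct raw UMI strings: read multiplicity
  cannot change which molecules must exist, and it keeps instances small.
* A read whose candidate enumeration would exceed a cap (default 4096) is
  dropped with a warning rather than sinking the whole group; such reads
  carry implausible error loads anyway (the ≤ 3-error filter keeps products
  at ≤ 8 in practice).

## Monomer baselines

For benchmarking, reads can be collapsed to monomer UMIs by taking each
block's first base (deterministic) or a uniformly random position, then
deduplicated by distinct count (`naive`) or by the directional network
method: merge `v` into `u` when `Hamming(u, v) = 1` and
`count(u) ≥ 2·count(v) − 1`, visiting nodes by descending count. These are
minimal re-implementations so no external deduplication tool is needed.

## The simulator

Amplification is a Galton–Watson branching process. At cycle `i` with pool
size `m`, `n ~ Binomial(m, α)` templates are chosen uniformly without
replacement and each yields one copy, so `m' = m + n` exactly and
`E[m_final] = m0(1+α)^c`. Base errors follow a second branching process: a
cycle synthesizing `t` bases draws `v ~ NBinom(r, q)` with `q = 1 − P_e`,
`r = qt` (real-valued `r`, i.e. the Pólya parameterization;
`E[v] = t·P_e`), places the `v` errors uniformly without replacement among
the `t` newly synthesized bases — templates are never retouched — and
substitutes each hit base by one of the other three uniformly. Sequencing
draws `depth` reads (without replacement when the pool is large enough,
with replacement otherwise) and reuses the same error machinery with the
sequencing error rate. Indels are not simulated: the substitution-only
model matches the error process above; indel handling is exercised
separately through the codec's re-segmentation DP on constructed fixtures.

Defaults are the simulated study conditions: 50 molecules, 12-base monomer
UMIs (36-base homotrimers), 12 cycles, amplification rate 0.85 (middle of
the 0.8–1.0 operating range), PCR error rate 3.6×10⁻⁶, sequencing depth
400, sequencing error rate 10⁻³, 50 replicates. Error-rate sweeps cover
10⁻⁷–10⁻¹. Reads carry only the UMI; transcript bodies are out of scope.
Every read keeps its founding-molecule id through amplification, sampling
and error injection, so methods are scored against exact ground truth.

`MoleculePool` supports a sequence-free mode (`seqs=None`) that tracks only
ancestry arrays; branching-moment studies over 1000 replicates use it since
sequences play no role in the amplification process itself. The same
`amplify_cycle` code path serves both modes.

What the simulator does *not* emulate: per-sequence amplification
efficiency, polymerase bias, chimeras, quality-score structure, and indels.
Passing tests therefore demonstrate correctness of the counting machinery
under a substitution-dominated error model — consistent with the
observation that most identifier errors are substitutions — not performance
on any particular instrument's full error profile.

### A note on error-free identity

With all error rates at zero, every method reports exactly the number of
distinct molecules *actually sequenced* in every replicate (asserted in the
tests). That number is occasionally 49 rather than 50: a molecule family in
the small-size tail of the branching distribution can be missed entirely by
a uniform 400-read sample of an ~80 000-read pool (roughly 0.5% per family,
so a fifth to a quarter of replicates typically contain a dropout). This is
a sampling-coverage property of subsampled sequencing, not a correction
error, and no deduplication method can recover a molecule that was never
sequenced.

## CMI evaluation

A common molecular identifier (CMI) is one known homotrimer sequence —
`GGGAAACCCTTTGGGCCCTTTAAACCCTTT`, monomer `GACTGCTACT` — attached to every
molecule. Any deviation is an error by construction. `score_cmi` reports
the fraction of reads exactly matching the expected sequence
(pre-correction), the fraction whose majority-vote collapse matches the
expected monomer (post-correction), and the Hamming-distance histogram.
Reads whose extracted CMI length differs from 30 cannot enter a Hamming
comparison; they are tallied as indel-suspect, or rescued by the
re-segmentation DP when enabled. Because every molecule carries the same
identifier, the deduplicated count of every gene should be exactly 1;
`per_gene_overcount` measures the fraction of genes meeting that.

## Indel re-segmentation

The homotrimer design tolerates indels in principle (a shifted block still
mostly agrees with itself), and the package makes that concrete with a
dynamic program: partition a length-shifted segment into B chunks, each
chunk costing its substitutions-to-homopolymer plus `|len − 3|`, with the
total indel budget capped (default 2). Short chunks are padded with `N` —
which can never win a vote — rather than inventing observations; long
chunks drop minority bases first, preserving the vote. This algorithm is
this package's own design; the tests show it rescues single insertions and
deletions.

## Read structure extraction

Orientation uses poly-A/T runs of ≥ 9 bases (configurable): a poly-T run
means the read is flipped. Note that a homotrimer UMI can itself contain a
long T run (consecutive T blocks); pipelines where reads are known to be
forward should disable orientation. Anchor search is leftmost
mismatch-tolerant sliding-window matching (default ≤ 2 mismatches; bulk
anchor `GTACTCTGCGTTGATACCACTGCTT`, droplet anchor `GTACTCTGCGTT`). The UMI
is cut adjacent to the anchor (side configurable), the barcode beyond it,
and both are appended to the read name with `_` delimiters. The droplet
path rejects reads whose barcode+UMI segment is shorter than 48 bases —
the filter is applied as a minimum because a complete trimer barcode+UMI
segment (3×16 or 3×12 + 3×12) cannot be shorter and still contain every
block. Barcode whitelists keep the `expected_cells` most frequent barcodes
(ties at the cutoff included); reads are assigned to the unique whitelist
entry within 2 mismatches, ambiguous reads left unassigned. Gene
assignment joins the SAM `XT` tag with the read-name UMI, with a
three-column TSV fallback.

## Numerical and determinism choices

All randomness flows through `numpy.random.Generator`; simulations spawn
independent child streams per replicate from a single seed
(`SeedSequence.spawn`), so outputs are byte-stable. Greedy ties,
whitelist ranking, node-visit order in directional networks and group
iteration order are all made deterministic (lexicographic tie-breaks,
sorted keys). Degenerate inputs (empty groups, all reads filtered, empty
pools, unorientable reads) signal rather than crash: empty results with
logged reasons, `None` signals for inconclusive collapses, typed exceptions
for contract violations.

## Problem sizes in the test suite

The bundled studies use 200 random groups for solver validation, 50
replicates for identity and sweep studies (seven PCR error rates,
10⁻⁷–10⁻¹), 1000 amplify-only replicates for branching moments, and 300
draws at t = 10⁶ bases for the error-injection moment — sizes chosen so the
whole suite completes in a few minutes on one core while keeping Monte
Carlo standard errors well below the tested tolerances (3 SE bounds).

## Known limitations

* The set-cover count is a parsimony estimate: it reports the *fewest*
  molecules consistent with the observations and can undercount when two
  true molecules are mutually consistent with one monomer.
* The directional baseline implements the published threshold rule only —
  no per-position qualities, no cluster/adjacency variants.
* The exact solver is exponential by design and restricted to validation
  scale.
* Whitelisting uses plain frequency ranking, not a knee-point detector.
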