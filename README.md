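# trimercount

Accurate molecule counting from sequencing reads tagged with **homotrimer
UMIs** — unique molecular identifiers in which every base is synthesized as
a triplet block (`b -> bbb`).

## Why

UMIs let you collapse PCR duplicates to absolute molecule counts, but PCR
and sequencing substitutions corrupt them: a corrupted UMI looks like a new
molecule and inflates the count, increasingly so with more PCR cycles.
Because a homotrimer UMI carries each base three times, errors become
*visible* (the block disagrees with itself) and *correctable* (the block's
majority base wins). `trimercount` implements the full correction stack for
bulk and single-cell transcriptomics:

* **trimer codec** — encode/collapse homotrimer UMIs, per-block majority
  vote, error-load counting and read filtering, indel re-segmentation;
* **set-cover deduplication** — when a block is inconclusive (three
  distinct bases), reads of a gene are resolved jointly: the molecule count
  is the smallest set of monomer UMIs `c` (one observed base per block,
  `c ∈ C(s)`) explaining every read `s ∈ S`. Greedy solver with the
  `(ln|S|+1)` guarantee for production; exact solver (exhaustive or ILP via
  HiGHS) as a validation oracle;
* **PCR/sequencing simulator** — Galton–Watson amplification
  (`m⁽ⁱ⁺¹⁾ = m⁽ⁱ⁾ + n⁽ⁱ⁾`, `n ~ Binom(m, α)`) with negative-binomial error
  injection (`v ~ NBinom(qt, q)`, `q = 1 − Pₑ`, so `E[v] = t·Pₑ`) and full
  ground-truth tracking;
* **CMI evaluation** — accuracy against a known spike-in identifier
  (`GGGAAACCCTTTGGGCCCTTTAAACCCTTT`), pre/post correction, per-gene
  overcount assessment;
* **monomer baselines** — first/random-base collapse, naive distinct
  counting, and the directional network method
  (`count(u) ≥ 2·count(v) − 1` at Hamming distance 1);
* **read structure** — poly-A/T orientation, mismatch-tolerant anchor
  search, UMI/barcode extraction, barcode whitelisting, SAM `XT`-tag gene
  joining.

## Worked example

Three reads of one gene, where the third read's first block `ACT` is
inconclusive — no majority exists, so the reads are resolved jointly by set
cover:

```python
>>> from trimercount import dedup_group
>>> res = dedup_group(["AAACCC", "AATCCC", "ACTCCC"])
>>> res.molecule_count, res.method, res.collapsed
(1, 'setcover', ('AC',))
```

The monomer `AC` uses a base observed in every block of every read, so one
molecule explains all three reads — the two disagreeing blocks were
substitution errors.

End to end, with simulated ground truth (50 true molecules, 12-base UMIs,
12 PCR cycles at a deliberately harsh 1% per-base PCR error rate, 400 reads
sequenced, 5 replicates):

```python
>>> from trimercount import SimConfig, run_simulation, evaluate_methods
>>> cfg = SimConfig(pcr_err=1e-2, perm_num=5, seed=42)
>>> df = evaluate_methods(run_simulation(cfg))
>>> print(df.groupby("method")[["count", "abs_deviation", "frac_recovered"]].mean().round(2))
             count  abs_deviation  frac_recovered
method
directional   87.2           37.2            0.87
majority      80.4           30.4            0.99
naive        215.4          165.4            0.96
setcover      50.0            0.8            0.97
```

Naive monomer counting reports ~215 molecules where 50 exist; the
directional network method absorbs some of the inflation; homotrimer
majority voting most of it; majority voting plus set cover recovers the
true count almost exactly.

The same workflows are available from the shell:

```sh
trimercount simulate -umi_num 50 -umi_len 12 -pcr_num 12 -perm_num 5 \
    -pcr_err 0.01 --seed 42 -o sim/
trimercount evaluate --sim-dir sim/ -o eval/
trimercount dedup -i tagged_reads.tsv --method setcover -o counts/
```

`simulate` writes `reads.fastq`, `truth.tsv`, `cycle_stats.tsv` and the
resolved `config.json`; `dedup` accepts a gene-tagged SAM/BAM (`XT` tag,
UMI as the final `_`-token of the read name) or a three-column TSV, and
writes a TSV count table (plus a Matrix Market matrix with barcode/feature
sidecars in `--cell-barcodes` mode).

## Layout

```
src/trimercount/
  codec.py       trimer blocks, majority vote, error counting, indel DP
  setcover.py    candidate enumeration, greedy + exact covers, group dedup
  baselines.py   first/random-base collapse, directional networks
  sim.py         branching-process simulator and method evaluation
  readstruct.py  orientation, anchors, extraction, whitelists, gene tags
  cmi.py         spike-in identifier scoring and per-gene overcounting
  io.py          FASTQ/TSV/MTX/JSON plumbing
  cli.py         `trimercount` subcommands
docs/methods.md  model, assumptions, design choices, limitations
```
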