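# triosv

Structural-variant (SV) analysis of a three-genome canid trio — dog,
gray wolf and dhole — built as a fully testable, desk-scale pipeline.
The scientific question it addresses: which large genomic variants
(insertions, deletions, inversions, translocations, repeats) arose on the
dog lineage during domestication, and can individual candidates — in
particular an insertion carrying an intact retro-inserted gene copy — be
verified at population level and shown to be expressed?

It is aimed at comparative-genomics practitioners who want the whole chain
of reasoning — pairwise whole-genome alignment, alignment-geometry SV
classification, lineage intersection, read-depth verification, and
paralog-aware expression — in one importable, seedable package with exact
synthetic ground truth.

## What it computes

**Alignment.** A chain/net pairwise aligner in the UCSC tradition:
exact k-mer-seeded maximal-match anchors (k = 15, repetitive k-mers
masked), sparse dynamic programming into maximally scoring colinear chains
with affine gap costs, then greedy netting to a single-coverage (on the
target) hierarchy of best chains. Chains competing for one target interval
before netting are kept as duplication evidence.

**SV classification.** For adjacent blocks of one chain with target gap
`gT` and strand-adjusted query gap `gQ` (SV floor 50 bp):

* `gT >= 50 > gQ` → insertion (INS); `gQ >= 50 > gT` → deletion (DEL);
  both large → a paired INS + DEL;
* a run of blocks on the opposite strand of its flanking context →
  inversion (INV); a run whose query chromosome (or position, beyond a
  jump threshold) breaks a syntenic context → translocation (TRA);
* alignment overlap on either sequence — two chains claiming one target
  interval, or one query interval aligned by two target regions → repeat
  (REP, i.e. duplication).

**Lineage specificity.** Both comparisons share the dog as target, so SVs
present in dog–wolf *and* dog–dhole (same type, compatible coordinates)
arose on the dog branch. The base-level analogue partitions every genome
into content aligned to both, exactly one, or neither of the other two
genomes.

**Verification and expression.** Per-sample read depth is normalized by
sequencing depth; the candidate insertion's regional mean is contrasted
with two equal-length flanks and tested between carriers and non-carriers
with the Mann–Whitney–Wilcoxon rank-sum test (exact for small tie-free
samples, normal approximation with tie/continuity corrections otherwise).
Expression of the retrocopy vs its parent uses RPKM in a 200 bp window
centred on their single diagnostic site, counting only allele-informative
reads: `RPKM = n / ((w/1000) · (N/10^6))`.

**Synthetic trio.** An ancestral genome is evolved along
`(dhole,(wolf,dog))` with branch-specific substitutions and planted,
non-overlapping SVs of all five classes, plus a spliced (intron-less) gene
copy re-inserted on the dog branch with exactly one diagnostic
substitution. Because events are placed in ancestor coordinates, the
simulator emits *exact* truth alignments and per-genome event coordinates,
so every downstream stage is benchmarked against ground truth.

## Worked example

`examples/01_simulate_and_call_svs.py` simulates a 2 × 150 kb trio with
5 events per type per branch, aligns dog against wolf and calls SVs:

```
simulated 76 events; dog genome 302,346 bp
aligned: 2444 gapless blocks in 39 chains
calls by type: {'REP': 10, 'INS': 11, 'DEL': 10, 'INV': 10, 'TRA': 10}
vs truth (breakpoints within 10 bp): recall=100.0% precision=100.0%
```

Each comparison sees its target-branch events as-is and the query-branch
events type-swapped (a wolf insertion is a dog deletion), hence 10 calls
per type from 5 + 5 planted events; the extra INS is the retrocopy.
`examples/03_read_depth_verification.py` shows the population check:

```
dog   normalized depth: insertion 0.999  flanks 1.000
wolf  normalized depth: insertion 0.010  flanks 1.000
rank-sum U = 132, two-sided p = 5.55e-05 (asymptotic)
```

and `examples/04_paralog_expression.py` the windowed RPKM at a simulated
2:1 expression ratio (`RPKM ratio parent/retro = 1.90`).

The full pipeline, from config to a deterministic `summary.tsv`, runs as

```
trio-sv run-all --seed 1 --outdir run1
```

with `simulate`, `align`, `callsv`, `lineage`, `venn`, `annotate`,
`verify` and `xprs` also available as individual subcommands over files.

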