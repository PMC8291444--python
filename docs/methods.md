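# Methods

This note documents the models, parameter choices and limitations behind
`triosv`. Coordinates are 0-based half-open in memory; report files meant
for humans print 1-based inclusive intervals and say so in their header.

## Synthetic trio generator

The generator is the package's source of ground truth, not a fixture: it
defines the conditions under which every downstream claim is tested.

An ancestral genome (default 3 chromosomes × 500 kb of uniform random
sequence) evolves along the species tree `(dhole,(wolf,dog))`. Each branch
(the two terminal canid branches, the dhole branch, and optionally the
wolf+dog internal branch) receives:

* **substitutions** at `subst_rate` per site (default 0.005/branch, so
  roughly 1% dog–wolf and 1.5% dog–dhole pairwise divergence — the
  closely-related regime the anchor aligner is designed for);
* **planted SVs** of five classes, by default 20 per type per terminal
  branch: INS (novel random sequence), DEL, INV (reverse-complemented in
  place), TRA (cut-and-paste of an interval onto another chromosome), and
  REP (a tandem second copy of an interval). Lengths are log-normal with
  median 200 bp and log-sd 0.7, truncated to [50, 3000] bp; 50 bp is the
  SV floor used throughout.

All events are placed in *ancestor* coordinates by rejection sampling,
mutually non-overlapping, at least 500 bp apart and 2× the maximum SV
length away from chromosome ends. Non-overlap is a deliberate
simplification (real genomes nest events) that makes recall and precision
unambiguous; the 500 bp spacing guarantees anchorable sequence between
events — two adjacent events with no flanking homology between them are
not resolvable as distinct calls by any alignment method. Because events
never overlap, each genome's coordinate map to the ancestor is a clean
segment list, and pairwise **truth alignments** are computed exactly by
intersecting two maps through ancestor coordinates. Tandem copies map to
the same ancestor interval, so truth alignments faithfully reproduce the
double-alignment signature of duplications.

A **retrocopy** is planted as one additional dog-branch insertion whose
sequence is the spliced (intron-less) transcript of a multi-exon gene,
carrying exactly one diagnostic substitution at its midpoint. Gene models
(default 8, 2–5 exons, '+' strand) are placed in reserved, event-free
regions so annotation semantics stay clean.

Everything flows from a single integer seed; identical configs are
byte-identical across runs.

What the generator does **not** emulate: repeat families (LINE/SINE
landscapes), nested/overlapping SVs, heterozygosity and diploidy,
sequencing error beyond a uniform stray-coverage fraction, and spliced
read alignment. Passing tests therefore demonstrate correctness of the
method's logic under clean conditions, not performance on real repeat-rich
mammalian assemblies.

## Anchor/chain/net aligner

* **Anchors** are maximal exact matches seeded by shared 15-mers, minimum
  length 20 bp, on both strands. k-mers containing N never seed; k-mers
  occurring more than 10 times in either genome are skipped (the spirit of
  repeat masking at this scale). Minus-strand anchors use strand-space
  query coordinates (positions on the reverse complement, the MAF
  convention), so coordinates increase along every chain.
* **Chaining** is sparse DP over anchors sorted by target start: chain
  score = Σ anchor lengths − Σ gap costs, with an affine cost
  `gap_open + gap_extend·(dt+dq)` (defaults 10 and 0.05). The defaults are
  set *below* the minimum anchor score so that every colinear anchor
  links; SV detection does not rely on chains breaking at SVs but on the
  gap geometry *within* chains. Successive anchors may overlap by up to
  15 bp (junction micro-homology extends both flanking exact matches
  across a breakpoint); the successor is trimmed. The predecessor search
  is banded (window 64) — a heuristic that is exact on small instances and
  on near-colinear data.
* **Netting** takes chains greedily by descending score (minimum kept
  score 25, below the 50 bp SV floor so the short second chain of a
  minimal duplication survives), trims anchor parts overlapping
  already-kept anchor bases, and records every trimmed interval as an
  overlap pair — pre-net duplication evidence.
* **Refinement** extends netted block edges through inter-block gaps,
  stepping over mismatches while a lookahead window (8 bp, ≥ 60% matching)
  still votes for homology. This recovers breakpoints at (near) base
  resolution when a substitution within a seed length of the true
  breakpoint truncated the terminal anchor; an extension never re-consumes
  query sequence its own chain already aligns. Overlap pairs are likewise
  merged per chain pair and sharpened, stopping where the dropped chain's
  alignment coincides with the kept one (beyond the duplicated footprint
  the two alignments agree and cease to be duplication evidence); merged
  raw overlaps under 20 bp are discarded as chance edge contacts.

## SV classification

Classification reads netted blocks sorted by target coordinate; the same
routine serves the aligner path (chain identity known) and any two-row
MAF (chains reconstructed from colinearity). Rules, in order:

1. Blocks overlapping on the target (truth-alignment duplications) emit
   REP and are reduced to the copy colinear with the left context.
2. Runs of blocks (same query chromosome, strand and chain) are tested
   against their flanking context: a foreign query chromosome — or a
   same-chromosome displacement beyond 10 kb — within a syntenic context
   (flanks continuing within 50 bp of each other on the query) is a TRA;
   an opposite-strand run in a same-chromosome context is an INV. When
   both apply, TRA wins (chromosome identity is stronger evidence). A
   "translocated" run whose query interval is *also* aligned by other
   target regions is duplicated sequence (e.g. a retrocopy aligning back
   to its parent locus), not a translocation: it is demoted and excluded
   from gap arithmetic, letting the enclosing chain's gap surface as the
   insertion it is.
3. Adjacent chain-runs whose query spans overlap by ≥ 50 bp, and query
   intervals covered twice by near-tandem target regions (multi-coverage,
   projected to the target through the second copy's diagonal), emit REP.
4. Between consecutive same-chain blocks with gaps `gT`/`gQ` (small
   mutual overlaps ≤ 25 bp trimmed): INS when only `gT` ≥ 50, DEL when
   only `gQ` ≥ 50, a paired INS+DEL when both (the five-type scheme has no
   "complex" class). An INS-like gap whose interior re-aligns query
   sequence used nearby by its own chain is a bridged tandem duplication
   and becomes REP with copy length `gT − gQ`; when genome sequences are
   available, gap content that is tandem-periodic (each base matching one
   period left or right at ≥ 80% identity, period jitter ± 2 bp) is
   likewise classified REP even with no witness chain.
5. Gap-derived indels that merely re-describe an INV/TRA/REP locus — the
   flank chain's bridge over an inversion, the donor-site "deletion" of a
   translocation (query-side overlap with the TRA's query interval) — are
   suppressed, so each event yields one call.
6. REP calls from several evidence routes are consolidated per locus:
   overlap-pair fragments (complementary witnesses of one duplicated
   footprint) are unioned; all other evidence types witness *rotations*
   of the duplication, so the longest single witness is kept — a union of
   rotations would overstate the copy length.

Tandem duplications of identical copies are intrinsically
rotation-ambiguous: any length-L window of the 2L duplicated region
represents the event equally well. Benchmarking therefore matches REP
calls on copy length and locus rather than exact junctions; all other
types are matched on breakpoints (± 10 bp for the aligner path; exact for
the truth path).

## Lineage intersection and sequence content

Both pairwise call sets live on dog coordinates, so the three-way
intersection needs no multiple-alignment engine: calls match when they
have the same type and agree positionally — indels by breakpoint distance
(≤ 50 bp) plus length ratio (≥ 0.5; a DEL's target interval is a point,
so reciprocal overlap is undefined for it), INV/TRA by reciprocal overlap
(≥ 0.5), REP by length ratio plus locus distance within one copy length
(rotation ambiguity again). Matching is greedy one-to-one on canonically
sorted inputs, hence order-independent.

The base-level partition marks, per genome pair, every aligned base (plus
sub-SV-floor gaps between colinear blocks — substitution noise, not
missing homology) and assigns each non-N base of each genome to exactly
one of four categories. The categories sum to the non-N genome length by
construction, and this is asserted at run time. Note the deliberate
distinction between *event*-specific and *content*-specific: a retrocopy
insertion is a dog-specific SV, but its inserted sequence still aligns to
the parent locus and is therefore not dog-specific content.

## Annotation

Each SV receives exactly one category by precedence
CDS > UTR > exon_noncoding > intron > intergenic over all overlapped gene
models (CDS-first is conservative for the question of how often SVs hit
coding sequence; the order is configurable). UTR means exonic-minus-CDS.
Lookup uses interval trees; a brute-force per-base scan serves as the test
oracle. "Fully covers a gene" means transcript-span containment within the
insertion interval; the pipeline allows 10 bp of slack because
aligner-path breakpoints are accurate to a few bases (the library default
is strict containment). The retrocopy signature compares the covered
gene's sequence against spliced transcripts of multi-exon genes elsewhere
(edit-distance identity ≥ 0.98 with at least one removed intron).

## Population verification

Depth normalization divides each sample's per-base raw depth by its
genome-wide mean sequencing depth (supplied per sample; unsequenced bases
are 0); species profiles average normalized depth base-by-base; the
regional mean over the candidate interval is contrasted with two flanks of
exactly the insertion's length, contiguous with it. Group comparison uses
the two-sided Mann–Whitney–Wilcoxon test: exact enumeration when the
pooled sample is ≤ 12 and tie-free, otherwise the normal approximation
with tie and continuity corrections; a pooled-constant input returns p = 1
with a degeneracy flag. Both branches sit on `scipy.stats.mannwhitneyu`,
cross-checked in tests against an independent rank-enumeration oracle and
Monte-Carlo calibrated at the 11-vs-12 design (type-I error at α = 0.05
measured within [0.04, 0.06]). Two-sidedness is an explicit choice.
`overlap_ratio` is the fraction of query-set records touching (≥ 1 bp) a
merged reference set — the cross-check used against independent
population call sets, which this package consumes but never re-implements.

## Paralog expression

Windows of width 200 bp (twice the read length; the site at index w/2,
left-biased for even w) are centred on the single diagnostic site; only
reads covering the site with the expected allele count (ambiguous reads
may be given a configurable weight, default 0, because strict
allele-informative counting is the only scheme that cleanly separates
near-identical paralogs). RPKM uses the whole simulated library as the
denominator (configurable). The simulator's read placements put
site-covering reads at their true locus and randomize ambiguous ones,
emulating multi-mapping; with strict counting the recovered ratio is a
binomial estimate of the true expression ratio, and tests hold it to
three binomial standard errors at 30 000 reads.

## Pipeline and determinism

`run_all` chains the stages with one config and one seed (sub-seeds are
fixed offsets of the master seed); `summary.tsv` is byte-identical across
reruns, and stage logs echo parameters so every summary number traces to
config. The CLI is a thin wrapper; all logic lives in the library. The
spec-scale run (3 × 500 kb, 20 events/type/branch) completes in roughly a
minute on one CPU; tests use a 2 × 120 kb trio with 4 events/type for the
same logic at interactive speed.

## Known limitations

* The aligner targets the closely-related regime (≲ 2–3% divergence);
  anchors vanish as divergence grows and no substitution matrix or gapped
  extension stands in for them.
* Repeat-rich or low-complexity sequence would flood the k-mer index;
  the max-occurrence filter is a stand-in for proper repeat masking.
* Nested and overlapping SVs are out of scope end-to-end (simulator and
  classifier); nested inversions, if present in real input, surface as
  separate strand runs rather than a hierarchy.
* The paired INS+DEL convention for substitution blocks means one complex
  locus yields two calls by design.
* REP breakpoints are reported modulo rotation; consumers needing a
  canonical junction should left-align against the reference themselves.
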