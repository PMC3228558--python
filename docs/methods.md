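# Methods

## The detection model

NumtS detection is posed as local alignment of a circular mitochondrial
reference (the query, ~16.6 kb) against nuclear sequence (the subject),
under BLASTN-style scoring: match +2, mismatch −3, and affine gaps where a
gap of length *g* costs 5 + 2*g* (open −5, extend −2, the extension
charged for every gapped base including the first). Every local alignment
whose raw score clears a significance floor is a High Scoring Pair (HSP);
chains of nearby, consistently oriented HSPs are then merged into
assembled NumtS.

### Seed-and-extend aligner

The internal aligner mirrors the classic BLASTN architecture so that
external BLASTN tabular output and the internal search are
interchangeable inputs to assembly:

* **Seeding** — exact 11-mers (the BLASTN default word size) of the query
  are indexed; subject k-mers are streamed against the index. K-mers
  containing N never seed, and N scores as a mismatch everywhere.
* **Clustering** — seed hits are grouped by diagonal (new group at
  diagonal jumps > 50) and split at subject gaps > 2 kb. Clusters with
  fewer than 3 seeds must pass a cheap ungapped X-drop extension
  (trigger score 40, X = 40): this discards the background of random
  11-mer matches without running gapped DP on them.
* **Gapped extension** — each surviving cluster is resolved with a banded
  Smith–Waterman with affine gaps over a window extending 1 kb beyond the
  seeded region on both axes, with the band padded 50 diagonals beyond
  the seeds' diagonal spread. The DP is exact within its band; the in-row
  gap recurrence is computed in closed form with a max-plus prefix scan,
  which makes each row a constant number of vectorised operations. The
  1 kb margin covers unseeded alignment tails: even at the lowest
  identity of interest (63%) the expected spacing between exact 11-mer
  seeds is ~160 bp, so a tail longer than 1 kb without a single seed is
  far outside detectability anyway.
* **Strand handling** — minus-strand hits come from running the identical
  search against the reverse complement of the subject and mapping
  subject coordinates back; the mitochondrial interval of every HSP is
  therefore always expressed on the mitochondrial plus strand, which
  keeps all downstream interval arithmetic strand-agnostic.
* **Culling** — among HSPs that overlap on both axes on the same strand
  (same alignment found from two clusters), the highest score wins, ties
  to the leftmost nuclear start. Output order is deterministic.

**Significance.** The published protocol fixed E ≤ 1e−3, but an E-value
depends on internals (Karlin–Altschul parameters, effective search-space
corrections) that differ between implementations. The internal aligner
therefore filters on a raw score ≥ 62 by default: 62 is exactly the score
of a 31 bp perfect match — the shortest fragment in the reference human
compilation — and approximates E ≈ 1e−3 for a mitochondrial-genome query
against a mammalian-genome-scale subject under Karlin–Altschul statistics
with λ ≈ 0.625, K ≈ 0.41 (exposed as configuration; HSPs are annotated
with approximate E-values on this basis). Parsed BLAST tables keep their
own E-value column and are filtered strictly below the threshold.

### Assembly rules

Two HSPs on the same chromosome merge when

1. they lie on the same strand;
2. their nuclear gap (start of the later minus end of the earlier) is
   **strictly less than** 2000 bp — overlaps (negative gaps) always pass;
3. their oriented mitochondrial gap is **at most** 2000 bp, where the gap
   runs h1 end → h2 start on the plus strand and h2 end → h1 start on the
   minus strand (successive nuclear blocks descend along the
   mitochondrial coordinate when the alignment is inverted), taken as
   min(linear gap, linear gap mod L) on the circular genome of length L.

The asymmetric bounds (strict vs inclusive) follow the protocol's wording
literally; both are configurable for sensitivity analysis. The circular
minimum generalises the control-region device — the D-loop is annotated
as the tail of the linearised reference followed by its head, so a
junction-spanning insertion surfaces as two HSPs whose linear
mitochondrial gap is hugely negative but whose circular gap is ~0 — to
any circular reference without special-casing the junction coordinates.

Assembly is the **transitive closure** of this pairwise relation:
connected components of the full pairwise mergeable graph within each
(chromosome, strand) group, computed by union-find. Transitivity is what
accommodates chains interrupted by long repetitive elements, where a
distant pair is bridged by intermediate blocks. Note the closure is taken
over *all* pairs, not only nuclear-adjacent ones: the mitochondrial-gap
condition is not monotone along the nuclear sort, so an adjacent-only
sweep can miss a merge that the pairwise graph contains.

A chain is flagged as wrapping the junction when some adjacent oriented
pair merges only via the around-the-origin route (linear gap ≤ −L/2 with
circular gap within bounds); its mitochondrial span is then reported as
start > end. The roll-up identity of a chain is the
alignment-length-weighted mean of member identities — the compilation
reports only per-HSP identities, so this derived aggregate is the least
surprising choice and is labelled as such in outputs.

IDs are assigned in output order (karyotype order 1..22, X, Y, then
other names lexicographically; nuclear start within a chromosome):
`HSA_NumtS_xxx` zero-padded to three digits (growing naturally past 999),
with `_bN` suffixes for members of multi-block chains only.

## Statistics

* **Coverage profile** — counts[p] = number of HSPs covering
  mitochondrial position p, via a difference array; exported as
  run-length-encoded bedGraph.
* **Per-chromosome table** — count, summed span and percentage of
  chromosome covered, percentages rounded half-away-from-zero to three
  decimals (spreadsheet convention, matching the published table's
  formatting). The span is the outer envelope of each NumtS by default;
  a sum-of-member-lengths mode is provided because the published table
  does not state which roll-up it used (its column totals also disagree
  with the companion text by ~0.3%, a discrepancy this package reports
  faithfully and does not attempt to reconcile).
* **Quartiles** — linear interpolation of order statistics (index
  (n−1)·q), the common spreadsheet default; configurable through
  `numpy.quantile` methods if a different convention is wanted.
* **Pearson correlation** — implemented from the definition; raises on
  zero variance.
* **Flank repeat content** — fraction of the up-to-2×1000 bp flanking
  bases covered by the union of supplied repeat intervals, flanks
  truncated at chromosome ends; summarised as a cumulative distribution
  at 1% bins.

## Liftover

Two mitochondrial references are globally aligned (Needleman–Wunsch with
the same scoring scheme; the DP is delegated to Biopython's
`PairwiseAligner` and decomposed into gapless blocks). Pairs below 90%
alignment identity are refused as non-homologous. Intervals are lifted by
their endpoints: a boundary inside an aligned block maps exactly; at a
target-side insertion the start of an interval takes the smaller image
and the end the larger (outward snapping, flagged), so a lifted
annotation never loses coverage; intervals wholly inside a source-only
segment are unmapped. The map is always computed from the two supplied
sequences — no indel coordinates are hard-coded.

## Tracks

Score shading is linear: BED score = round(identity × 10), clipped to
[0, 1000], deliberately *not* rescaled to the observed 63–100% range so
scores are comparable across datasets (a bit-score mode would be the
alternative reading of "similarity score"; identity is the default).
Chromosome colours ship as an editable TSV following the genome browser's
conventional karyotype palette. Reciprocal nuclear↔mitochondrial links —
hyperlinks in a browser — are realised in flat files by shared item names
plus a crosslink TSV of paired locus strings.

## The synthetic-data generator

The generator emulates the features of real NumtS that the pipeline must
handle; its defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| fragment length | 31 bp–15 kb, log-uniform | the real compilation spans 31–~15 kb with median ~215 bp: strongly right-skewed |
| target identity | 63–100%, uniform | observed similarity range vs the modern reference |
| indel rate | 5e−4 /bp | substitutions dominate post-insertion divergence; indels are rare and short (geometric, mostly length 1) |
| minus strand | p = 0.5 | insertion orientation is unbiased |
| split implants | p = 0.2, 2–4 blocks, spacers 200–1900 bp | emulates repeat-interrupted insertions; spacers stay below the 2 kb merge radius so the assembler should rejoin them |
| junction-spanning | p = 0.05 | exercises the circular merge rule |
| implant separation | ≥ 2500 bp | distinct insertions stay more than one merge radius apart, so truth identity is well defined |

Two structural minima keep sampled features meaningful: each arm of an
origin-crossing fragment spans ≥ 100 bp and each sub-block of a split
implant ≥ 150 bp. A fragment with a vestigial (few-bp) arm or block would
not instantiate the feature its parameter requests — nothing observable
crosses the junction, and a 10 bp "block" is not a fragment — so such
degenerate draws are excluded by construction.

Realised identity is bookkept from the mutation log (matches over
matches + mismatches + inserted + deleted), never by re-alignment, so
ground truth is independent of the aligner under test. The background is
i.i.d. uniform ACGT; an optional tandem-repeat injector
(`repeat_fraction`) emulates the repeat-rich neighbourhoods most real
NumtS inhabit but is off by default — passing tests on clean background
demonstrate detection and assembly correctness, not robustness to
repeat-induced ambiguity, segmental duplications, or assembly-quality
artefacts of real genomes.

Recovery scoring matches detections to truth by reciprocal overlap ≥ 0.5
(of each interval), assigned greedily by descending overlap, one-to-one.
With zero detections precision is reported as 1.0 by convention, with a
`zero_detection` flag. Merge accuracy is the fraction of split implants
recovered as exactly one assembled NumtS.

## Problem sizes and numerics

The test and acceptance workloads run the full pipeline on simulated
chromosomes of 120–300 kb with 5–30 implants — large enough that every
code path (both strands, splits, junction wraps, marginal scores) is
exercised, while a run completes in seconds. Oracle checks use
Biopython's full Smith–Waterman on ≤ 5 kb windows and brute-force
connected components / per-column walks at small n. DP scores are exact
integers, so oracle score comparisons are equalities; alignment *ends*
may differ from an oracle's by a few bases when co-optimal trims exist,
hence the ±5 bp coordinate tolerance. All randomness flows through
`numpy.random.default_rng` seeds; identical inputs and seeds give
byte-identical outputs everywhere, including the CLI.

## Known limitations

* The aligner is exact only within its band; a hit whose optimal
  alignment drifts more than ~50 diagonals beyond its seeds' spread
  (i.e. >50 bp of net indel between seeds) could be scored sub-optimally.
  Irrelevant at simulated indel rates, and bounded in practice by the
  seed-spread-adaptive band.
* E-values are Karlin–Altschul approximations; the primary significance
  filter is the raw-score floor.
* The per-chromosome reference table ships with the package for
  statistics reproduction; the full per-fragment hg18 catalogue is not
  reproduced (it requires the original genome build and BLAST binary).
* Liftover handles exactly two references (no chaining through a third)
  and consumes only maps built by the package itself.
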