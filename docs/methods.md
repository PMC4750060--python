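# Methods

This note records the models, conventions, numerical choices and
limitations behind `plastrace`, in the order of the analysis stages.

## Genomes and coordinates

Genomes are circular nucleotide sequences over `{A,C,G,T,N}` with typed,
stranded features. Coordinates are 1-based inclusive throughout (the
GenBank dialect); conversion to Python's 0-based slices happens only at
module boundaries. Features may wrap the origin on circular genomes
(`end < start`). Ambiguity codes other than `N` are rejected at parse
time — the plastomes this toolkit targets contain none, and failing fast
beats silently miscounting composition. Multi-exon `join()` locations are
flattened to one feature per exon plus a derived `intron` feature between
consecutive exons. GC content is `(G + C) / (A + C + G + T)` with `N`
excluded from the denominator; percentages are formatted with half-up
rounding to two decimals, matching the way plastome composition tables are
printed.

## Repeat screens

**SSRs.** A locus is a maximal perfect run of a primitive 1–6 bp motif
meeting the per-motif-length copy thresholds (mono ≥ 10, di ≥ 5, tri- to
hexa- ≥ 4 — the values plastome surveys conventionally use). Primitivity
prevents double counting (`AAAA` is a mononucleotide run, never `AA`
twice); trailing partial copies are trimmed so the reported span is an
exact whole-copy concatenation. Loci are individual: no compound-SSR
merging, because class-wise totals (mono + di + tri + tetra) must add up
to the overall count. Motifs are reported as found; strand complements are
not merged. The screen is linear; a hypothetical SSR spanning the circular
origin is not reported.

**Tandem repeats.** The detector is a deterministic seed-and-extend
design, not a reimplementation of any probabilistic tandem-repeat model:
identical 13-mers at spacing `d` (30 ≤ `d` ≤ sequence/2) vote for a
period; each voted region grows whole copies left and right while the
adjacent-copy identity stays at or above the floor (0.90 by default), then
takes partial-copy overhangs base by base. Identity between adjacent
copies is matches / aligned columns of a global alignment in which gap
columns count as mismatches. Overlapping calls are deduplicated by most
copies, then smallest unit — the "nested or redundant calls removed" rule.
Because the dialect differs from other tandem finders, equality with any
particular published array count is treated as a soft check, not a hard
test; on the package's own synthetic data the detector is exact.

**Region classes.** A locus takes the class covering its start position,
with precedence exon (CDS/tRNA/rRNA) > intron > intergenic spacer.

## Rearrangement model

Genome organisations are signed circular permutations of `n` block
identifiers (33 blocks in the motivating data set). Two readings are the
same genome when they differ by rotation or whole-circle reflection; the
canonical form rotates block 1 to the front and reflects if needed to make
it positive. An inversion is a pair of junction cut points `0 ≤ i < j ≤ n`;
the blocks between them are order-reversed and sign-flipped.

**Distance.** The circular distance is computed by fixing block 1 as the
frame: on a circle, inverting a segment and inverting its complement give
the same genome, so every sorting scenario can be rewritten to avoid the
frame block, reducing the problem to a linear signed permutation of
`m = n − 1` elements. The linear distance is the exact Hannenhalli–Pevzner
formula `d = (m + 1) − c + h + f`: `c` counts breakpoint-graph cycles;
hurdles `h` are the unoriented components whose points form a single
contiguous arc among all unoriented-component points on the (circularised)
point line; the fortress indicator `f` is 1 when there are oddly many
hurdles and each one protects an otherwise-hidden hurdle. Component
computation is a union-find over interleaving gray-edge spans — quadratic
in the worst case, which is irrelevant at these block counts.

**Oracle.** An independent breadth-first search over canonicalized circular
states certifies the distance: the test suite demands *zero* discrepancies
against the formula, exhaustively for `n ≤ 4` and on 1000 seeded pairs at
each of `n = 5, 6`. Any mismatch is treated as a release blocker for the
formula implementation. (The BFS cannot reach fortress-sized permutations;
that part of the formula follows the standard theory and is exercised only
indirectly.)

**Scenarios.** `sort_by_reversals` walks greedily: among all inversions
lowering the distance by one — at least one always exists — it takes the
smallest left cut, then smallest right cut. The result is deterministic,
optimal-length, and replays to the target.

**Trees.** `mgr_tree` follows the MGR idea: repeatedly apply, to some
genome, the inversion that maximally decreases the sum of its distances to
the other genomes (ties broken by lexicographic inversion, then input
order), merging lineages into a named ancestor whenever two genomes
coincide; if no inversion helps, the closest pair is walked together one
optimal step. Internal nodes are named `A<k>` with `k` continuing past the
leaf count, the usual convention for reconstructed ancestral plastome
organisations. With a fixed topology only the internal labels are
optimised: exact medians (full state-space scoring) for `n ≤ 6`, otherwise
single-inversion hill climbing. The heuristic is not guaranteed optimal;
tests assert only the parsimony-side bounds (never worse than a planted
history, never worse than a leaf spanning path).

## Repeat tracing

Repeat copies are zero-length oriented markers, because the mechanism
argument operates at gene-order resolution; a copy is anchored at a block
junction (with a slot index when several copies share one junction) or
inside a block (internal copies travel and flip with their block; their
fractional offset only expresses "inside LCB k"). When an inversion cut
point lands at a copy-bearing junction, a slot choice says how many copies
stay outside the segment on that side; slots count outward-in on each
side, which makes a traced inversion with explicit slots an involution.
The default (all copies stay outside the segment) is resolved per state
and is therefore *not* self-inverse when copies move — scenario files that
need reversibility state slots explicitly, as the bundled worked scenarios
do.

The narrated fixtures encode only the blocks the text names (LCBs 1, 2,
11, 12, 25, 29) in their narrated adjacencies; the other 27–28 blocks are
fillers. That is sufficient: the classification of the traced copies is a
pure function of the configuration and never depends on filler identity.
The splitting theorem — a tandem pair becomes a dispersed inverted pair
iff exactly one cut separates the two copies — is checked exhaustively
over every endpoint/slot placement on 6–8-block toys.

## Nuclear gene structure

Introns are inferred purely from the gap blocks of an affine-gap global
alignment of the genomic copy against its transcript (match 2, mismatch
−4, open −12, extend −0.2: one long gap is preferred over scattered
ones). GT..AG conformance is reported as an annotation, never enforced,
since a 5'-UTR intron gives the aligner no protein-level signal to lean
on. Offsets use the translation start convention: the A of ATG is +1, the
base immediately 5' is −1, so an intron between the bases 65 and 64
positions upstream reports −65/−64. Exon mismatches are reported as
candidate RNA-editing sites, not errors. The ORF is the longest ATG→stop
frame on the forward strand (transcript orientation is known), with a
warning below 50 codons. Protein percent identity is matches / aligned
columns of a BLOSUM62 global alignment (open −11, extend −1) with no
end-gap forgiveness, so 1.0 implies identity; because this figure depends
on aligner parameters, comparisons against any published identity value
are soft checks only.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic per seed, and truth holds by construction:

- Background sequence registers every 13-mer (none may repeat — 13 is
  also the tandem screen's seed size, so the background can contribute no
  seed match) and keeps every 1–6 bp periodicity at least two copies below
  the SSR thresholds, relaxing to one copy only if all four bases are
  otherwise forbidden. Plants are made maximal by forcing the flanking
  base on each side to break the plant's own periodicity. Tandem units are
  themselves screened (as a self-concatenation) so an array cannot contain
  an incidental SSR.
- Planted inversion histories record every inversion with its slots;
  `PlantedHistory.verify()` replays them. With `k ≤ 8` random inversions
  on 33 blocks the reversal distance equals `k` in ≳95% of trials (random
  cuts occasionally share a junction and partially cancel, so equality
  cannot be universal; the distance can never exceed `k`).
- Gene pairs are built transcript-first; introns get boundary bases that
  mismatch their flanks so the alignment gap cannot slide, making planted
  coordinates recoverable with zero tolerance. UTRs are scrubbed of ATG so
  the planted ORF is unambiguous; upstream regions are scrubbed of the
  promoter motif except where planted.

Passing on this synthetic data shows the detectors are exact under their
own assumptions — perfect repeats on repeat-free backgrounds, identical
exons, single-copy motifs. Real plastomes violate all of these (imperfect
repeats, shared k-mers everywhere, editing sites), so synthetic recall of
1.0 bounds, but does not measure, field performance. The default synthetic
genome is 20 kb (scalable to the ~140 kb of a real plastome); test and
acceptance runs use 8–20 kb genomes, 500-trial history samples and
150-pair scenario samples, sizes chosen to keep the whole suite in the
seconds range while leaving every assertion exact rather than statistical
where the design permits.

## Known limitations

- Only the inversion (reversal) model is implemented — no transpositions,
  block interchanges or DCJ; that matches the unichromosomal circular
  reversal model the analysis is framed in.
- LCB decomposition is an input (GRIMM-style files), not computed; a
  shared-gene-order fallback (`gene_order`) covers genomes annotated with
  single-copy genes.
- The MGR tree is a greedy heuristic; for data sets where the true tree
  matters, fix the topology and let the package optimise labels only.
- The tandem screen reports the leftmost frame of an array; coordinates of
  degenerate arrays with internal indels may differ from other dialects.
- Accession-based figures (genome length, GC, published repeat counts)
  require the deposited records; the package analyses any GenBank file
  handed to it but ships no downloaded data.
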