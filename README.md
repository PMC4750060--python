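# plastrace

Comparative analysis toolkit for rearrangement-prone plastomes: repeat
screens, exact signed reversal distances between gene orders, parsimony
trees with ancestral genome organisations, and a mechanism engine that
traces duplicated genes through inversion scenarios.

## The scientific problem

Conifer chloroplast genomes that have lost one copy of the canonical
inverted repeat rearrange extensively, and several lineages
(Cupressaceae, Taxaceae, Cephalotaxaceae) carry a *short* inverted repeat
(sIR) around the tRNA gene *trnQ*-UUG instead. One proposed origin of such
an sIR is a two-step mechanism: the gene first duplicates in place, forming
a tandem repeat, and a later genome inversion whose cut point falls
*between* the two copies carries one of them away in flipped orientation —
two dispersed copies in opposite orientations, i.e. an sIR.

`plastrace` implements everything needed to examine that argument on
gene-order data:

- **Repeat screens** (`plastrace.repeats`): perfect microsatellite (SSR)
  loci with the classical thresholds (≥10 copies for mononucleotide
  motifs, ≥5 for dinucleotide, ≥4 for tri- to hexanucleotide), and a
  deterministic seed-and-extend tandem-repeat finder (unit ≥ 30 bp,
  adjacent-copy identity ≥ 0.90).
- **Rearrangement algebra** (`plastrace.rearrangement`): signed circular
  permutations of locally collinear blocks (LCBs); the exact
  Hannenhalli–Pevzner inversion distance
  `d = (m + 1) − c + h + f` (breakpoint-graph cycles `c`, hurdles `h`,
  fortress `f`) under the unichromosomal circular model; optimal inversion
  scenarios; a breadth-first-search oracle certifying the distance for
  small block counts; and an MGR-style parsimony tree labelling internal
  nodes with ancestral gene orders.
- **Repeat tracing** (`plastrace.repeat_trace`): oriented repeat copies
  anchored at block junctions (or inside blocks) are propagated through
  inversions, with explicit control over which gap is cut when a cut point
  lands at a copy-bearing junction; arrangements are classified as tandem,
  adjacent-inverted, dispersed-forward, dispersed-inverted (the sIR), or
  mixed.
- **Nuclear gene structure** (`plastrace.gene_transfer`): ORF discovery and
  translation, intron detection by global genomic-vs-transcript alignment,
  upstream promoter-motif scans, and protein percent identity — the
  analyses used to characterise a plastid gene functionally relocated to
  the nucleus (n-*accD*).
- **Synthetic data** (`plastrace.synthetic_data`): deterministic generators
  whose outputs carry exact ground truth — repeat-free backgrounds with
  planted SSRs/tandem arrays, planted inversion histories, and
  genomic/transcript pairs with planted introns.

## Worked example

Tracing the tandem *trnQ* pair through the two narrated inversions
(`python examples/05_trnq_repeat_tracing.py`):

```
Sciadopitys-like   loci=1 class=tandem_forward
    trnQ-UUG#1 (+) at JunctionAnchor(left=-25, right=1, slot=0)
    trnQ-UUG#2 (+) at JunctionAnchor(left=-25, right=1, slot=1)
A22                loci=1 class=tandem_forward
    trnQ-UUG#1 (+) at JunctionAnchor(left=2, right=1, slot=0)
    trnQ-UUG#2 (+) at JunctionAnchor(left=2, right=1, slot=1)
Taxus-like         loci=2 class=dispersed_inverted
    trnQ-UUG#1 (-) at JunctionAnchor(left=1, right=-2, slot=0)
    trnQ-UUG#2 (+) at JunctionAnchor(left=-11, right=1, slot=0)
```

The tandem pair starts between LCB 25 and LCB 1; the first inversion moves
it, still tandem, next to LCB 2; the second inversion cuts between the two
copies, leaving one copy by LCB 2 and one by LCB 1 in opposite orientations
— the short inverted repeat. The second scenario (Cupressaceae ancestor →
*Cunninghamia*-like order) ends with three *trnQ* loci, two copies in one
orientation and one opposite.

Reversal distances recover planted histories exactly
(`python examples/03_reversal_distance.py`):

```
planted inversions: 5, inferred reversal distance: 5
optimal scenario (5 steps):
  step 1: invert between junctions 0 and 13
  ...
replay reaches the derived order: True
```

The other examples cover genome statistics, the repeat screens, the
parsimony tree with ancestor recovery, and the nuclear-gene stage (93 bp
intron at −65/−64, 212-aa ORF, TATA box at −1599).

A thin CLI exposes the same stages (`plastrace stats`, `plastrace repeats
ssr|tandem`, `plastrace rearr dist|sort|tree`, `plastrace trace
run|classify`, `plastrace accd orf|intron|scan`, `plastrace synth ...`,
`plastrace pipeline run`).

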