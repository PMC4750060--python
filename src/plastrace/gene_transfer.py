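"""Gene-structure analysis of a plastid gene relocated to the nucleus.

When a plastid gene (here the accD β-carboxyltransferase subunit) moves to
the nuclear genome, its nuclear copy acquires eukaryotic gene features: a
promoter with a TATA box far upstream, untranslated regions and spliceosomal
introns.  Comparing the genomic copy against its mature transcript exposes
the introns as alignment gaps; the open reading frame and its protein are
recovered from the transcript; and the protein can be compared with the
plastid-encoded homologues of related species.

Offset convention: the A of the translation-start ATG is ``+1`` and the base
immediately 5' of it is ``-1`` (so an intron lying between the bases 65 and
64 positions upstream of the ORF is reported at ``-65/-64``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "IntronCall",
    "GeneStructure",
    "longest_orf",
    "find_introns",
    "scan_promoter",
    "percent_identity",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class IntronCall:
    """One intron: genomic coordinates plus ORF-relative flank offsets.

    ``five_offset``/``three_offset`` are the ORF-relative offsets of the
    exonic bases immediately flanking the intron (negative = upstream of the
    translation start); an intron in the 5' UTR sitting between the bases at
    -65 and -64 is reported as ``(-65, -64)``.
    """

    start: int  # genomic, 1-based inclusive
    end: int
    length: int
    five_offset: int
    three_offset: int
    gt_ag: bool  # annotation only; splice sites are not enforced


@dataclass(frozen=True)
class GeneStructure:
    """ORF span, introns, UTR lengths and promoter hits on the genomic copy."""

    orf_start: int  # genomic, 1-based
    orf_end: int
    introns: tuple[IntronCall, ...] = ()
    utr5_len: int = 0
    utr3_len: int = 0
    promoter_hits: tuple[tuple[str, int], ...] = ()
    exon_mismatches: tuple[int, ...] = ()  # candidate RNA-editing sites


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------


def longest_orf(
    transcript: str, min_codons: int = 50
) -> tuple[str, int, int]:
    """Longest ATG-to-stop reading frame on the forward strand.

    Returns ``(protein, start, end)`` with 1-based transcript coordinates of
    the ORF including its stop codon; the protein excludes the stop.  If no
    ORF reaches ``min_codons`` codons a warning is attached to the best
    available ORF.
    """
    import warnings

    seq = transcript.upper().replace("U", "T")
    best: Optional[tuple[int, int]] = None  # (start0, end0) incl. stop
    i = seq.find("ATG")
    starts = []
    while i != -1:
        starts.append(i)
        i = seq.find("ATG", i + 1)
    for s in starts:
        for j in range(s + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in _STOPS:
                if best is None or (j + 3 - s) > (best[1] - best[0]):
                    best = (s, j + 3)
                break
    if best is None:
        raise ValueError("no ATG...stop open reading frame found")
    start0, end0 = best
    n_codons = (end0 - start0) // 3 - 1  # excluding the stop
    if n_codons < min_codons:
        warnings.warn(
            f"longest ORF has only {n_codons} codons (< {min_codons}); "
            "returning best available",
            stacklevel=2,
        )
    protein = str(Seq(seq[start0 : end0 - 3]).translate())
    return protein, start0 + 1, end0


# ---------------------------------------------------------------------------
# intron detection
# ---------------------------------------------------------------------------


def _genomic_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -4.0
    a.open_gap_score = -12.0
    a.extend_gap_score = -0.2
    return a


def find_introns(genomic: str, transcript: str) -> GeneStructure:
    """Infer introns by globally aligning the genomic copy to its transcript.

    The transcript is expected to be the genomic sequence minus the introns;
    each maximal gap in the transcript row of the affine-gap global
    alignment is called as one intron.  Splice sites are inferred purely
    from the alignment gap; GT..AG conformance is reported as an annotation,
    not enforced.  Exonic mismatch positions (candidate RNA editing) are
    reported, not treated as errors.
    """
    genomic = genomic.upper()
    transcript = transcript.upper().replace("U", "T")
    aligner = _genomic_aligner()
    aln = aligner.align(genomic, transcript)[0]
    row_g, row_t = aln[0], aln[1]

    # map transcript coordinates and find gap blocks in the transcript row
    gaps: list[tuple[int, int, int]] = []  # (gen_start0, gen_end0, tx_before0)
    mism: list[int] = []  # transcript positions (0-based) of exon mismatches
    g_pos = t_pos = 0
    gap_open: Optional[int] = None
    for cg, ct in zip(row_g, row_t):
        if ct == "-" and cg != "-":
            if gap_open is None:
                gap_open = g_pos
            g_pos += 1
        else:
            if gap_open is not None:
                gaps.append((gap_open, g_pos - 1, t_pos))
                gap_open = None
            if cg == "-":
                t_pos += 1  # insertion in transcript (not expected)
            else:
                if cg != ct:
                    mism.append(t_pos)
                g_pos += 1
                t_pos += 1
    if gap_open is not None:
        gaps.append((gap_open, g_pos - 1, t_pos))

    protein, orf_start_t, orf_end_t = longest_orf(transcript)

    def tx_offset(t0: int) -> int:
        """ORF-relative offset of 0-based transcript position t0."""
        pos1 = t0 + 1
        return pos1 - orf_start_t + (1 if pos1 >= orf_start_t else 0)

    introns = []
    for gs, ge, t_before in gaps:
        seqi = genomic[gs : ge + 1]
        introns.append(
            IntronCall(
                start=gs + 1,
                end=ge + 1,
                length=ge - gs + 1,
                five_offset=tx_offset(t_before - 1),
                three_offset=tx_offset(t_before),
                gt_ag=seqi.startswith("GT") and seqi.endswith("AG"),
            )
        )

    # ORF genomic coordinates: shift transcript coordinates by upstream introns
    def to_genomic(t1: int) -> int:
        g = t1
        for it in sorted(introns, key=lambda x: x.start):
            if it.start <= g:
                g += it.length
        return g

    orf_start_g = to_genomic(orf_start_t)
    orf_end_g = to_genomic(orf_end_t)
    return GeneStructure(
        orf_start=orf_start_g,
        orf_end=orf_end_g,
        introns=tuple(introns),
        utr5_len=orf_start_t - 1,
        utr3_len=len(transcript) - orf_end_t,
        exon_mismatches=tuple(p + 1 for p in mism),
    )


# ---------------------------------------------------------------------------
# promoter scan
# ---------------------------------------------------------------------------


def scan_promoter(
    upstream: str, motif: str = "TATA", window: Optional[int] = None
) -> list[int]:
    """Exact-match motif offsets in the upstream region.

    ``upstream`` is the sequence immediately 5' of the translation start
    (its last base is at offset -1).  Offsets are reported for the first
    base of each motif occurrence, as negative numbers, nearest first.  A
    window larger than the available sequence is truncated with a warning.
    """
    import warnings

    upstream = upstream.upper()
    motif = motif.upper()
    if window is not None:
        if window > len(upstream):
            warnings.warn(
                f"window {window} exceeds available upstream sequence "
                f"({len(upstream)} bp); truncated",
                stacklevel=2,
            )
            window = len(upstream)
        upstream = upstream[-window:]
    hits = []
    i = upstream.find(motif)
    while i != -1:
        hits.append(i - len(upstream))
        i = upstream.find(motif, i + 1)
    hits.sort(reverse=True)  # nearest to the start first
    return hits


# ---------------------------------------------------------------------------
# protein comparison
# ---------------------------------------------------------------------------


def percent_identity(
    prot_a: str,
    prot_b: str,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> float:
    """Global-alignment identity: matches / aligned columns (gaps count).

    BLOSUM62 with affine gaps; identical inputs give exactly 1.0 and there
    is no end-gap forgiveness, so 1.0 implies identity.
    """
    if not prot_a or not prot_b:
        raise ValueError("empty protein sequence")
    if prot_a == prot_b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(prot_a, prot_b)[0]
    ra, rb = aln[0], aln[1]
    cols = len(ra)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return matches / cols
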