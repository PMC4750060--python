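"""Repeat screens: SSR detection and a tandem-repeat finder.

Two screens are implemented natively:

* :func:`find_ssrs` — perfect simple-sequence-repeat (microsatellite) loci
  with motif lengths 1–6 bp, using the classical MISA-style thresholds
  (10 copies for mononucleotide motifs, 5 for dinucleotide, 4 for tri- to
  hexanucleotide).  Only maximal perfect runs are reported, each once under
  its primitive motif; motifs are reported as found (strand complements are
  not merged) and compound SSRs are not merged — each locus stands alone.

* :func:`find_tandem_repeats` — larger tandem arrays (unit >= 30 bp, >= 2
  copies, adjacent-copy identity >= 0.90 by default).  This is a
  deterministic seed-and-extend design: shared k-mers at equal spacing vote
  for a period, candidate arrays are refined by aligning adjacent copies
  with a global aligner, and nested or redundant calls are removed by
  keeping, among overlapping calls, the one with most aligned copies and
  then the smallest unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio import Align

from .genome_io import AnnotatedGenome

__all__ = [
    "SSRLocus",
    "TandemRepeat",
    "DEFAULT_SSR_THRESHOLDS",
    "find_ssrs",
    "classify_ssr_regions",
    "find_tandem_repeats",
]

#: minimum whole-copy counts per motif length, as used for plastome screens
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSRLocus:
    """A perfect microsatellite locus (1-based inclusive coordinates)."""

    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    region_class: Optional[str] = None  # CDS / intron / IGS

    def __post_init__(self):
        if self.end - self.start + 1 != self.unit_len * self.copies:
            raise ValueError("span must equal unit_len * copies")
        if _minimal_period(self.motif) != len(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem array of >= 2 near-identical copies of a >= 30 bp unit."""

    unit_len: int
    copies: float
    identity: float
    start: int
    end: int
    consensus: str


def _minimal_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)  # pragma: no cover


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def find_ssrs(
    seq: str, thresholds: Optional[dict[int, int]] = None
) -> list[SSRLocus]:
    """Maximal perfect SSR runs above the per-motif-length copy thresholds.

    A run is reported once, under its primitive motif (``AAAA`` is a
    mononucleotide run, never dinucleotide ``AA``); trailing partial copies
    are trimmed so the locus spans whole copies only.  Loci are sorted by
    start coordinate.
    """
    if thresholds is None:
        thresholds = DEFAULT_SSR_THRESHOLDS
    seq = seq.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for u, min_copies in sorted(thresholds.items()):
        i = 0
        while i + u < n:
            # maximal window of period u starting at i
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            run_len = j - i
            copies = run_len // u
            if copies >= min_copies:
                motif = seq[i : i + u]
                window = seq[i : i + copies * u]
                if _minimal_period(window) == u and "N" not in motif:
                    loci.append(
                        SSRLocus(
                            motif=motif,
                            unit_len=u,
                            copies=copies,
                            start=i + 1,
                            end=i + copies * u,
                        )
                    )
                i = j - u + 1  # past this run; allow overlap into next period
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def classify_ssr_regions(
    loci: Sequence[SSRLocus], genome: AnnotatedGenome
) -> list[SSRLocus]:
    """Attach a region class (CDS / intron / IGS) to each locus.

    Precedence is exon (CDS, tRNA, rRNA) over intron over intergenic spacer;
    a locus overlapping two classes takes the class covering its start.
    """
    exons = genome.features_of_kind("CDS", "tRNA", "rRNA")
    if not exons:  # fall back to gene spans when only genes are annotated
        exons = genome.features_of_kind("gene")
    introns = genome.features_of_kind("intron")

    def covers(f, pos: int) -> bool:
        if f.end >= f.start:
            return f.start <= pos <= f.end
        return pos >= f.start or pos <= f.end  # origin wrap

    out = []
    for locus in loci:
        pos = locus.start
        if any(covers(f, pos) for f in exons):
            cls = "CDS"
        elif any(covers(f, pos) for f in introns):
            cls = "intron"
        else:
            cls = "IGS"
        out.append(replace(locus, region_class=cls))
    return out


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -0.5
    return a


def _copy_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Matches / aligned columns; gap columns count as mismatching."""
    if a == b:
        return 1.0
    aln = aligner.align(a, b)[0]
    cols = 0
    matches = 0
    sa, sb = aln[0], aln[1]
    for x, y in zip(sa, sb):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return matches / cols if cols else 0.0


def find_tandem_repeats(
    seq: str,
    min_unit: int = 30,
    min_identity: float = 0.90,
    min_copies: float = 2.0,
    k: int = 13,
    max_unit: Optional[int] = None,
) -> list[TandemRepeat]:
    """Deterministic seed-and-extend tandem-array detection.

    Equal k-mers at spacing ``d`` (``min_unit <= d <= max_unit``) vote for a
    periodic region of period ``d``; each voted region is refined by walking
    whole copies left and right while the adjacent-copy identity stays at or
    above ``min_identity``.  Overlapping calls are deduplicated by copy
    count, then smaller unit.
    """
    if min_unit < 1:
        raise ValueError("min_unit must be >= 1")
    seq = seq.upper()
    n = len(seq)
    if max_unit is None:
        max_unit = max(min_unit, n // 2)
    aligner = _aligner()

    # seed: positions sharing a k-mer at candidate period d
    index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    votes: dict[int, set[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a_i in range(len(positions)):
            for b_i in range(a_i + 1, len(positions)):
                d = positions[b_i] - positions[a_i]
                if min_unit <= d <= max_unit:
                    votes.setdefault(d, set()).add(positions[a_i])

    candidates: list[TandemRepeat] = []
    for d, pos_set in sorted(votes.items()):
        positions = sorted(pos_set)
        # cluster votes for the same period into runs
        clusters: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - clusters[-1][-1] <= d:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            tr = _refine_array(seq, cl[0], d, min_identity, aligner)
            if tr is not None and tr.copies >= min_copies:
                candidates.append(tr)

    return _dedupe(candidates)


def _refine_array(
    seq: str, anchor: int, d: int, min_identity: float,
    aligner: Align.PairwiseAligner,
) -> Optional[TandemRepeat]:
    """Grow an array of period ``d`` around ``anchor`` (0-based)."""
    n = len(seq)

    def ident(a0: int, b0: int) -> float:
        return _copy_identity(seq[a0 : a0 + d], seq[b0 : b0 + d], aligner)

    start = anchor
    # walk whole copies left, then right
    while start - d >= 0 and ident(start - d, start) >= min_identity:
        start -= d
    end = anchor  # start of last whole copy
    while end + 2 * d <= n and ident(end, end + d) >= min_identity:
        end += d
    n_whole = (end - start) // d + 1
    if n_whole < 2:
        return None
    # partial-copy overhangs: extend base-by-base while period d persists
    head = 0
    limit = min(d - 1, start)
    while head < limit and seq[start - 1 - head] == seq[start - 1 - head + d]:
        head += 1
    tail = 0
    limit = min(d - 1, n - (end + d))
    while tail < limit and seq[end + d + tail] == seq[end + tail]:
        tail += 1
    copies = n_whole + (head + tail) / d
    idents = [ident(start + i * d, start + (i + 1) * d) for i in range(n_whole - 1)]
    identity = sum(idents) / len(idents)
    consensus = seq[start : start + d]
    return TandemRepeat(
        unit_len=d,
        copies=round(copies, 2),
        identity=round(identity, 3),
        start=start - head + 1,
        end=end + d + tail,
        consensus=consensus,
    )


def _dedupe(calls: list[TandemRepeat]) -> list[TandemRepeat]:
    """Remove nested/redundant calls: most copies, then smallest unit wins."""
    calls = sorted(
        set(calls), key=lambda t: (-t.copies, t.unit_len, t.start)
    )
    kept: list[TandemRepeat] = []
    for c in calls:
        overlapping = any(
            not (c.end < k.start or k.end < c.start) for k in kept
        )
        if not overlapping:
            kept.append(c)
    kept.sort(key=lambda t: t.start)
    return kept
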