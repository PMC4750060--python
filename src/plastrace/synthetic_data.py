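"""Ground-truth generators for every input the analysis consumes.

All generators are deterministic per seed.  The guiding principle is that
truth must hold *by construction*:

* Background sequence is built so that it can never trigger a detector:
  every 13-mer is unique (no seed matches for the tandem screen) and no
  periodicity of 1–6 bp comes near the SSR copy thresholds.  Planted
  repeats are made maximal by forcing a mismatch at both array boundaries,
  so detectors must recover exactly the planted coordinates.
* Planted inversion histories record every inversion (with junction slot
  choices), so replaying them reproduces the result exactly and the true
  number of events is known.
* Genomic/transcript pairs are built transcript-first; introns are inserted
  with mismatching boundary bases so the alignment gap cannot slide and the
  planted coordinates are recovered with zero tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gene_transfer import GeneStructure, IntronCall
from .genome_io import AnnotatedGenome, Feature
from .rearrangement import (
    Inversion,
    InversionScenario,
    SignedCircularPermutation,
    all_inversions,
    apply_inversion,
)
from .repeat_trace import (
    RepeatConfiguration,
    RepeatCopy,
    TracedInversion,
    apply_inversion_traced,
)
from .repeats import DEFAULT_SSR_THRESHOLDS, SSRLocus

__all__ = [
    "PlantedHistory",
    "SSRPlant",
    "TandemPlant",
    "random_permutation",
    "evolve",
    "synth_genome",
    "synth_gene_pair",
    "synth_upstream",
]

ALPHABET = "ACGT"
KMER = 13  # background uniqueness window; matches the tandem screen seed


# ---------------------------------------------------------------------------
# permutations and histories
# ---------------------------------------------------------------------------


def random_permutation(n: int, seed: int) -> SignedCircularPermutation:
    """Uniform canonical signed circular permutation of ``n`` blocks."""
    if n < 3:
        raise ValueError("need n >= 3 blocks")
    rng = np.random.default_rng(seed)
    rest = list(range(2, n + 1))
    rng.shuffle(rest)
    signs = rng.integers(0, 2, size=n - 1)
    blocks = [1] + [b if s == 0 else -b for b, s in zip(rest, signs)]
    return SignedCircularPermutation(blocks)


@dataclass(frozen=True)
class PlantedHistory:
    """A known inversion history: source, recorded events, result."""

    seed: int
    source: SignedCircularPermutation
    inversions: tuple[TracedInversion, ...]
    result: SignedCircularPermutation
    source_config: Optional[RepeatConfiguration] = None
    result_config: Optional[RepeatConfiguration] = None

    @property
    def scenario(self) -> InversionScenario:
        return InversionScenario(tuple(t.inversion for t in self.inversions))

    def verify(self) -> bool:
        """Replaying the inversions on the source reproduces the result."""
        return self.scenario.replay(self.source) == self.result


def evolve(
    p: SignedCircularPermutation,
    k: int,
    seed: int,
    copies: Optional[Sequence[RepeatCopy]] = None,
) -> PlantedHistory:
    """Apply ``k`` random inversions, recording each one (with slots).

    If repeat ``copies`` are given, the configuration is traced alongside
    (default slot choices: copies stay outside the inverted segment).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    invs = all_inversions(p.n)
    cur = p
    config = RepeatConfiguration.build(p, copies) if copies is not None else None
    steps: list[TracedInversion] = []
    for _ in range(k):
        inv = invs[int(rng.integers(0, len(invs)))]
        step = TracedInversion(inv)
        steps.append(step)
        cur = apply_inversion(cur, inv)
        if config is not None:
            config = apply_inversion_traced(config, step)
    return PlantedHistory(
        seed=seed,
        source=p,
        inversions=tuple(steps),
        result=cur,
        source_config=(
            RepeatConfiguration.build(p, copies) if copies is not None else None
        ),
        result_config=config,
    )


# ---------------------------------------------------------------------------
# constrained background sequence
# ---------------------------------------------------------------------------


class _SeqBuilder:
    """Incremental sequence builder enforcing background cleanliness.

    Background characters must not (a) repeat any 13-mer already present
    anywhere in the sequence, nor (b) let any 1–6 bp periodicity reach
    within two copies of the SSR reporting thresholds.  Plant characters
    are appended verbatim (their k-mers are still registered, so background
    near a plant cannot echo it).
    """

    def __init__(self, rng: np.random.Generator,
                 thresholds: dict[int, int] = DEFAULT_SSR_THRESHOLDS):
        self.rng = rng
        self.chars: list[str] = []
        self.kmers: set[str] = set()
        self.runs = {p: 0 for p in range(1, 7)}  # period-p window ending here
        self.thresholds = thresholds

    def _advance_runs(self, c: str) -> dict[int, int]:
        i = len(self.chars)
        out = {}
        for p in range(1, 7):
            if i >= p and self.chars[i - p] == c:
                out[p] = self.runs[p] + 1
            else:
                out[p] = min(i + 1, p)
        return out

    def _register(self, c: str, runs: dict[int, int]):
        self.chars.append(c)
        self.runs = runs
        if len(self.chars) >= KMER:
            self.kmers.add("".join(self.chars[-KMER:]))

    def append_plant(self, plant: str):
        for c in plant:
            self._register(c, self._advance_runs(c))

    def append_background(self, length: int, forbid_first: str = ""):
        """Clean background characters; the first may exclude extra letters."""
        for idx in range(length):
            forbidden = set(forbid_first) if idx == 0 else set()
            placed = False
            for margin in (2, 1, 0):  # relax the safety margin if cornered
                order = self.rng.permutation(4)
                for oi in order:
                    c = ALPHABET[int(oi)]
                    if c in forbidden:
                        continue
                    runs = self._advance_runs(c)
                    if any(
                        runs[p] >= p * (self.thresholds[p] - margin)
                        for p in range(1, 7)
                    ):
                        continue
                    if len(self.chars) >= KMER - 1:
                        kmer = "".join(self.chars[-(KMER - 1):]) + c
                        if kmer in self.kmers:
                            continue
                    self._register(c, runs)
                    placed = True
                    break
                if placed:
                    break
            if not placed:  # pragma: no cover - 4 letters always leave room
                raise RuntimeError("background construction cornered")

    def sequence(self) -> str:
        return "".join(self.chars)


def _random_unit(rng: np.random.Generator, length: int) -> str:
    """A tandem unit whose self-concatenation contains no SSR-scale run."""
    for _ in range(50):
        b = _SeqBuilder(rng)
        b.append_background(length)
        unit = b.sequence()
        if _max_run_copies(unit * 2) is None:
            return unit
    raise RuntimeError("could not build a clean tandem unit")


def _max_run_copies(seq: str) -> Optional[tuple[int, int]]:
    """First (position, period) whose run reaches an SSR threshold, if any."""
    n = len(seq)
    for p in range(1, 7):
        run = p
        for i in range(p, n):
            run = run + 1 if seq[i] == seq[i - p] else p
            if run >= p * DEFAULT_SSR_THRESHOLDS[p]:
                return (i, p)
    return None


# ---------------------------------------------------------------------------
# synthetic annotated genome with planted repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSRPlant:
    """A perfect SSR to plant: primitive motif repeated ``copies`` times."""

    motif: str
    copies: int
    region: str = "IGS"  # CDS / intron / IGS


@dataclass(frozen=True)
class TandemPlant:
    """A tandem array: ``copies`` copies of a random ``unit_len`` bp unit.

    ``substitutions`` point mutations are scattered over the non-first
    copies to lower the adjacent-copy identity below 1.
    """

    unit_len: int = 40
    copies: int = 3
    substitutions: int = 0
    region: str = "IGS"


@dataclass
class _Segment:
    kind: str  # exon / intron / igs
    length: int
    gene: Optional[str] = None
    plants: list = field(default_factory=list)  # (rel_start, plant_str, spec)


def synth_genome(
    n_genes: int = 6,
    planted_ssrs: Sequence[SSRPlant] = (),
    planted_tandems: Sequence[TandemPlant] = (),
    seed: int = 0,
    length: int = 20000,
    genome_id: str = "synthetic",
) -> tuple[AnnotatedGenome, dict]:
    """A circular annotated genome with planted repeats and exact truth.

    The genome alternates intergenic spacers with genes (every third gene
    carries an intron); repeats are planted inside segments of the region
    class their spec requests.  Returns ``(genome, truth)`` where the truth
    dict holds the exact loci (``"ssrs"``: list of :class:`SSRLocus` with
    region classes; ``"tandems"``: list of dicts with unit/copies/coords).
    """
    rng = np.random.default_rng(seed)

    # ---- plan segments -----------------------------------------------------
    segments: list[_Segment] = []
    gene_len, intron_len = 900, 300
    for g in range(n_genes):
        segments.append(_Segment("igs", 0))
        name = f"gene{g + 1}"
        if g % 3 == 2:
            segments.append(_Segment("exon", gene_len // 2, gene=name))
            segments.append(_Segment("intron", intron_len, gene=name))
            segments.append(_Segment("exon", gene_len // 2, gene=name))
        else:
            segments.append(_Segment("exon", gene_len, gene=name))
    segments.append(_Segment("igs", 0))

    # ---- build plant strings ----------------------------------------------
    region_map = {"CDS": "exon", "intron": "intron", "IGS": "igs"}
    plants: list[tuple[str, str, object]] = []  # (segment kind, string, spec)
    for spec in planted_ssrs:
        motif = spec.motif.upper()
        if not motif or len(motif) > 6:
            raise ValueError("SSR motif must be 1-6 bp")
        plants.append((region_map[spec.region], motif * spec.copies, spec))
    for spec in planted_tandems:
        if spec.unit_len < 1:
            raise ValueError("unit_len must be >= 1")
        unit = _random_unit(rng, spec.unit_len)
        arr = list(unit * spec.copies)
        for _ in range(spec.substitutions):
            pos = int(rng.integers(spec.unit_len, len(arr)))
            old = arr[pos]
            arr[pos] = ALPHABET[
                (ALPHABET.index(old) + 1 + int(rng.integers(0, 3))) % 4
            ]
        plants.append((region_map[spec.region], "".join(arr), spec))

    # ---- assign plants to segments -----------------------------------------
    spacing = 60  # clean background flanking every plant inside its segment
    for kind, plant_str, spec in plants:
        candidates = [s for s in segments if s.kind == kind]
        if not candidates:
            raise ValueError(f"no segment of class {kind!r}; increase n_genes")
        # round-robin by current load; error when nothing fits
        candidates.sort(key=lambda s: sum(len(p[1]) for p in s.plants))
        seg = candidates[0]
        seg.plants.append((None, plant_str, spec))

    # IGS segments absorb the remaining length budget
    fixed = sum(s.length for s in segments if s.kind != "igs")
    igs_segments = [s for s in segments if s.kind == "igs"]
    budget = length - fixed
    min_igs = [
        max(200, sum(len(p[1]) + spacing for p in s.plants) + spacing)
        for s in igs_segments
    ]
    if sum(min_igs) > budget:
        raise ValueError("length too small for the requested plants/genes")
    extra = budget - sum(min_igs)
    for i, s in enumerate(igs_segments):
        s.length = min_igs[i] + extra // len(igs_segments)
    igs_segments[-1].length += extra % len(igs_segments)

    for s in segments:
        need = sum(len(p[1]) + spacing for p in s.plants) + spacing
        if s.plants and s.length < need:
            raise ValueError(
                f"plants overlap: segment of class {s.kind} too small"
            )

    # ---- lay out plants within segments ------------------------------------
    for s in segments:
        if not s.plants:
            continue
        gap = (s.length - sum(len(p[1]) for p in s.plants)) // (len(s.plants) + 1)
        cursor = gap
        placed = []
        for _, plant_str, spec in s.plants:
            placed.append((cursor, plant_str, spec))
            cursor += len(plant_str) + gap
        s.plants = placed

    # ---- assemble -----------------------------------------------------------
    builder = _SeqBuilder(rng)
    features: list[Feature] = []
    truth_ssr_loci: list[SSRLocus] = []
    truth_tandems: list[dict] = []
    abs_pos = 0
    for s in segments:
        seg_start = abs_pos
        cursor = 0
        for rel, plant_str, spec in s.plants:
            period = (
                len(spec.motif)
                if isinstance(spec, SSRPlant)
                else spec.unit_len
            )
            # the plant must not extend leftwards, so the background base
            # just before it may not continue the plant's periodicity
            builder.append_background(rel - cursor - 1)
            builder.append_background(1, forbid_first=plant_str[period - 1])
            start_abs = seg_start + rel  # 0-based
            builder.append_plant(plant_str)
            if isinstance(spec, SSRPlant):
                truth_ssr_loci.append(
                    SSRLocus(
                        motif=spec.motif.upper(),
                        unit_len=len(spec.motif),
                        copies=spec.copies,
                        start=start_abs + 1,
                        end=start_abs + len(plant_str),
                        region_class=spec.region,
                    )
                )
            else:
                truth_tandems.append(
                    {
                        "unit_len": spec.unit_len,
                        "copies": float(spec.copies),
                        "start": start_abs + 1,
                        "end": start_abs + len(plant_str),
                        "substitutions": spec.substitutions,
                    }
                )
            cursor = rel + len(plant_str)
            # and not rightwards: forbid the continuing-period base next
            builder.append_background(
                1, forbid_first=plant_str[len(plant_str) - period]
            )
            cursor += 1
        builder.append_background(s.length - cursor)
        abs_pos += s.length
        if s.kind == "exon":
            features.append(
                Feature("CDS", s.gene, seg_start + 1, abs_pos, "+")
            )
        elif s.kind == "intron":
            features.append(
                Feature("intron", s.gene, seg_start + 1, abs_pos, "+")
            )

    # one gene feature spanning all of each gene's exons and introns
    gene_span: dict[str, tuple[int, int]] = {}
    for f in features:
        lo, hi = gene_span.get(f.name, (f.start, f.end))
        gene_span[f.name] = (min(lo, f.start), max(hi, f.end))
    for name, (lo, hi) in gene_span.items():
        features.append(Feature("gene", name, lo, hi, "+"))

    genome = AnnotatedGenome(
        id=genome_id,
        seq=builder.sequence(),
        circular=True,
        features=tuple(features),
    )
    truth = {"ssrs": truth_ssr_loci, "tandems": truth_tandems}
    return genome, truth


# ---------------------------------------------------------------------------
# genomic/transcript pairs
# ---------------------------------------------------------------------------

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[int(i)] for i in rng.integers(0, 4, size=length))


def _scrub(seq: str, *motifs: str, rng: np.random.Generator) -> str:
    """Destroy every occurrence of the given motifs by mutating one base."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for motif in motifs:
            i = s.find(motif)
            if i != -1:
                pos = i + len(motif) // 2
                old = chars[pos]
                chars[pos] = ALPHABET[(ALPHABET.index(old) + 2) % 4]
                changed = True
                break
    return "".join(chars)


def synth_gene_pair(
    intron_specs: Sequence[tuple[int, int]],
    seed: int = 0,
    utr5_len: int = 200,
    orf_codons: int = 212,
    utr3_len: int = 150,
) -> tuple[str, str, GeneStructure]:
    """A genomic/transcript pair differing only by planted introns.

    ``intron_specs`` is a list of ``(five_offset, length)`` pairs: the
    intron of the given length sits immediately 3' of the exonic base at
    that ORF-relative offset (so ``(-65, 93)`` plants a 93 bp intron between
    the bases at -65 and -64, i.e. 64 bp upstream of the ATG).  The ORF
    encodes ``orf_codons`` amino acids.  Returns
    ``(genomic, transcript, truth)``.
    """
    rng = np.random.default_rng(seed)
    for off, ln in intron_specs:
        if ln < 1:
            raise ValueError("intron length must be >= 1")
        if off == 0:
            raise ValueError("offset 0 does not exist (+1 is the A of ATG)")

    # transcript: scrubbed UTRs so the planted ORF is the longest one
    utr5 = _scrub(_random_seq(rng, utr5_len), "ATG", rng=rng)
    codons = []
    while len(codons) < orf_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOP_CODONS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    utr3 = _scrub(_random_seq(rng, utr3_len), "ATG", rng=rng)
    transcript = utr5 + orf + utr3
    orf_start_t = utr5_len + 1

    # insert introns 3' to 5' so transcript coordinates stay valid
    def insertion_index(off: int) -> int:
        # offset -k (k>=1) is transcript position orf_start_t - k;
        # offset +k is position orf_start_t + k - 1; insert after it
        return orf_start_t + off if off < 0 else orf_start_t + off - 1

    specs = sorted(intron_specs, key=lambda t: -insertion_index(t[0]))
    genomic = transcript
    calls = []
    for off, ln in specs:
        at = insertion_index(off)
        if not (1 <= at < len(transcript)):
            raise ValueError(f"intron offset {off} outside the transcript")
        left, right = genomic[:at], genomic[at:]
        for _ in range(50):
            intron = "GT" + _random_seq(rng, ln - 4) + "AG" if ln >= 4 else (
                _random_seq(rng, ln)
            )
            if intron[0] != right[0] and intron[-1] != left[-1]:
                break
        else:  # fall back: free boundary bases, no GT..AG
            first = next(c for c in ALPHABET if c != right[0])
            last = next(c for c in ALPHABET if c != left[-1])
            intron = first + _random_seq(rng, ln - 2) + last
        genomic = left + intron + right
        calls.append((off, at, ln, intron))

    # truth structure in genomic coordinates (introns sorted 5'->3')
    calls.sort(key=lambda c: c[1])
    introns = []
    shift = 0
    for off, at, ln, intron in calls:
        gstart = at + shift + 1
        introns.append(
            IntronCall(
                start=gstart,
                end=gstart + ln - 1,
                length=ln,
                five_offset=off,
                three_offset=off + 1 if off != -1 else 1,
                gt_ag=intron.startswith("GT") and intron.endswith("AG"),
            )
        )
        shift += ln
    upstream_intron_len = sum(
        i.length for i in introns if i.five_offset < 0
    )
    orf_start_g = orf_start_t + upstream_intron_len
    internal = sum(
        i.length for i in introns if i.five_offset > 0
    )
    orf_end_g = orf_start_g + 3 * (orf_codons + 1) - 1 + internal
    truth = GeneStructure(
        orf_start=orf_start_g,
        orf_end=orf_end_g,
        introns=tuple(introns),
        utr5_len=utr5_len,
        utr3_len=utr3_len,
    )
    return genomic, transcript, truth


def synth_upstream(
    length: int = 1985,
    motif: str = "TATA",
    offsets: Sequence[int] = (-1599,),
    seed: int = 0,
) -> str:
    """An upstream (promoter-side) region with the motif planted exactly.

    The background is scrubbed of accidental motif matches, so a scan
    reports exactly the planted offsets.  Offsets are for the motif's first
    base, negative, with -1 the base immediately 5' of the translation
    start.
    """
    rng = np.random.default_rng(seed)
    for off in offsets:
        if not (-length <= off <= -len(motif)):
            raise ValueError(f"offset {off} outside a {length} bp window")
    motif = motif.upper()
    seq = _scrub(_random_seq(rng, length), motif, rng=rng)
    chars = list(seq)
    planted = set()
    for off in offsets:
        start = length + off
        chars[start : start + len(motif)] = motif
        planted.update(range(start, start + len(motif)))
    # planting can create overlap-induced extra matches; break them by
    # mutating a base outside every planted span
    for _ in range(4 * length):
        out = "".join(chars)
        bad = next(
            (
                i
                for i in range(length - len(motif) + 1)
                if out[i : i + len(motif)] == motif
                and (i - length) not in offsets
            ),
            None,
        )
        if bad is None:
            return out
        free = [p for p in range(bad, bad + len(motif)) if p not in planted]
        if not free:
            raise RuntimeError("planted motifs overlap each other")
        p = free[0]
        chars[p] = ALPHABET[(ALPHABET.index(chars[p]) + 2) % 4]
    raise RuntimeError("could not scrub accidental motif matches")
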