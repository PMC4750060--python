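"""Reading, writing and interrogating annotated (circular) genomes.

GenBank flat files are parsed with Biopython; internally every coordinate is
1-based inclusive (the GenBank dialect) and a genome may be circular, in
which case features are allowed to wrap the origin.  Multi-exon ``join()``
locations are flattened to one feature per exon plus a derived ``intron``
feature between consecutive exons.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, FeatureLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "GenomeParseError",
    "parse_genbank",
    "parse_fasta",
    "gc_content",
    "format_percent",
    "extract_feature_seq",
    "hamming_diff",
    "gene_order",
    "write_fasta",
    "write_feature_table",
]

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "IGS")
_VALID_BASES = set("ACGTN")


class GenomeParseError(ValueError):
    """Raised when a genome record cannot be parsed or validated."""


@dataclass(frozen=True)
class Feature:
    """A typed, stranded interval on a genome (1-based inclusive).

    ``end < start`` is only legal on a circular genome and denotes a feature
    wrapping the origin.
    """

    kind: str
    name: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and must be >= 1")

    def length(self, genome_length: Optional[int] = None) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrap-around feature needs the genome length")
        return genome_length - self.start + 1 + self.end


@dataclass(frozen=True)
class AnnotatedGenome:
    """A nucleotide sequence over {A,C,G,T,N} with typed features."""

    id: str
    seq: str
    circular: bool = True
    features: tuple[Feature, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq.upper()) - _VALID_BASES
        if bad:
            raise GenomeParseError(
                f"ambiguity codes other than N are not supported: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", self.seq.upper())
        object.__setattr__(self, "features", tuple(self.features))
        n = len(self.seq)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(
                    f"feature {f.name} ({f.start}..{f.end}) outside genome of length {n}"
                )
            if f.end < f.start and not self.circular:
                raise ValueError(
                    f"feature {f.name} wraps the origin but the genome is linear"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def feature_by_name(self, name: str, kind: Optional[str] = None) -> Feature:
        hits = [
            f
            for f in self.features
            if f.name == name and (kind is None or f.kind == kind)
        ]
        if not hits:
            avail = sorted({f.name for f in self.features})
            raise KeyError(f"no feature named {name!r}; available: {avail}")
        return hits[0]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_KEEP_TYPES = {"gene", "CDS", "tRNA", "rRNA"}


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product", "label"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return sf.type


def _flatten_biopython_feature(sf: SeqFeature, circular: bool) -> list[Feature]:
    """One Feature per exon part, plus derived introns between parts."""
    strand = "-" if (sf.location.strand or 1) < 0 else "+"
    name = _feature_name(sf)
    parts = sorted(sf.location.parts, key=lambda loc: int(loc.start))
    out: list[Feature] = []
    for loc in parts:
        out.append(
            Feature(
                kind=sf.type,
                name=name,
                start=int(loc.start) + 1,
                end=int(loc.end),
                strand=strand,
            )
        )
    for a, b in zip(parts, parts[1:]):
        istart, iend = int(a.end) + 1, int(b.start)
        if istart <= iend:
            out.append(
                Feature(kind="intron", name=name, start=istart, end=iend, strand=strand)
            )
    return out


def parse_genbank(path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Features of type gene/CDS/tRNA/rRNA are kept; ``join()`` locations yield
    one feature per exon and a derived intron between consecutive exons.
    """
    try:
        record: SeqRecord = SeqIO.read(path, "genbank")
    except Exception as exc:
        raise GenomeParseError(f"malformed GenBank record in {path}: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    feats: list[Feature] = []
    for sf in record.features:
        if sf.type in _KEEP_TYPES:
            feats.extend(_flatten_biopython_feature(sf, circular))
    seq = str(record.seq)
    if not seq:
        raise GenomeParseError(f"record {record.id} has no ORIGIN sequence")
    return AnnotatedGenome(
        id=record.id, seq=seq, circular=circular, features=tuple(feats)
    )


def parse_fasta(path) -> AnnotatedGenome:
    """Parse the first record of a FASTA file (no features)."""
    try:
        record = next(SeqIO.parse(path, "fasta"))
    except StopIteration:
        raise GenomeParseError(f"no FASTA record in {path}")
    return AnnotatedGenome(id=record.id, seq=str(record.seq))


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------


def _region_seq(genome: AnnotatedGenome, start: int, end: int) -> str:
    """Forward-strand bases of a 1-based inclusive, possibly wrapping region."""
    n = len(genome)
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"region {start}..{end} outside genome of length {n}")
    if end >= start:
        return genome.seq[start - 1 : end]
    if not genome.circular:
        raise ValueError("wrap-around region on a linear genome")
    return genome.seq[start - 1 :] + genome.seq[:end]


def gc_content(
    genome: AnnotatedGenome, region: Optional[tuple[int, int]] = None
) -> float:
    """(G + C) / (A + C + G + T) of the genome or a region; N is excluded."""
    seq = genome.seq if region is None else _region_seq(genome, *region)
    if not seq:
        raise ValueError("empty region")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("region contains no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Percentage rounded half-up, matching tabular presentation (35.42)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return str(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_feature_seq(genome: AnnotatedGenome, feature) -> str:
    """Feature sequence; minus-strand features are reverse-complemented.

    ``feature`` may be a :class:`Feature` or a feature name.
    """
    if isinstance(feature, str):
        feature = genome.feature_by_name(feature)
    raw = _region_seq(genome, feature.start, feature.end)
    return reverse_complement(raw) if feature.strand == "-" else raw


def hamming_diff(seq_a: str, seq_b: str) -> tuple[int, list[int]]:
    """Count and 1-based positions of mismatches between equal-length strings."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must be equal length ({len(seq_a)} vs {len(seq_b)}); align first"
        )
    positions = [i + 1 for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]
    return len(positions), positions


def gene_order(genome: AnnotatedGenome, gene_names: Sequence[str]):
    """Signed circular permutation of the listed genes by start coordinate.

    Block ``k`` is the k-th name in ``gene_names`` (1-based); the sign is the
    gene's strand.  Every listed gene must occur exactly once among the
    genome's ``gene`` features.
    """
    from .rearrangement import SignedCircularPermutation

    placed = []
    for k, name in enumerate(gene_names, start=1):
        hits = [f for f in genome.features if f.kind == "gene" and f.name == name]
        if not hits:
            raise KeyError(f"gene {name!r} not found in {genome.id}")
        if len(hits) > 1:
            raise ValueError(
                f"gene {name!r} occurs {len(hits)} times; disambiguate with copy suffixes"
            )
        f = hits[0]
        placed.append((f.start, k if f.strand == "+" else -k))
    placed.sort()
    return SignedCircularPermutation([s for _, s in placed])


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_fasta(genome: AnnotatedGenome, path) -> None:
    record = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([record], path, "fasta")


def write_feature_table(genome: AnnotatedGenome, path) -> None:
    """TSV feature table: name, kind, start, end, strand."""
    close = False
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("name\tkind\tstart\tend\tstrand\n")
        for f in genome.features:
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")
    finally:
        if close:
            fh.close()


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a minimal GenBank flat file (round-trips through parse_genbank)."""
    record = SeqRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA",
                           "topology": "circular" if genome.circular else "linear",
                       })
    # rebuild join() locations: exon parts of one gene are merged only when an
    # annotated intron of the same name bridges them, so duplicated genes
    # (e.g. two trnQ-UUG copies) are never collapsed into a bogus join
    introns = {
        (f.name, f.start, f.end)
        for f in genome.features
        if f.kind == "intron"
    }
    grouped: dict[tuple[str, str, str], list[Feature]] = {}
    order: list[tuple[str, str, str]] = []
    for f in genome.features:
        if f.kind in ("intron", "IGS"):
            continue
        key = (f.kind, f.name, f.strand)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(f)
    for kind, name, strand in order:
        parts = sorted(grouped[(kind, name, strand)], key=lambda f: f.start)
        runs: list[list[Feature]] = [[parts[0]]]
        for prev, cur in zip(parts, parts[1:]):
            if (name, prev.end + 1, cur.start - 1) in introns:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            locs = [
                FeatureLocation(f.start - 1, f.end, strand=1 if strand == "+" else -1)
                for f in run
            ]
            loc = locs[0] if len(locs) == 1 else sum(locs[1:], locs[0])
            record.features.append(
                SeqFeature(loc, type=kind, qualifiers={"gene": [name]})
            )
    SeqIO.write([record], path, "genbank")
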