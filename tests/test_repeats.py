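import pytest

from plastrace.genome_io import reverse_complement
from plastrace.repeats import (
    SSRLocus,
    classify_ssr_regions,
    find_ssrs,
    find_tandem_repeats,
)
from plastrace.synthetic_data import SSRPlant, TandemPlant, synth_genome

BG = "GATCCTGAACTGGTTACCTAGCTGATCGCATAGCAATCGGTCACTTAGGC"  # repeat-free filler


class TestFindSsrs:
    def test_mono_run_above_threshold(self):
        loci = find_ssrs(BG + "A" * 12 + BG[::-1])
        assert len(loci) == 1
        l = loci[0]
        assert (l.motif, l.unit_len, l.copies) == ("A", 1, 12)
        assert l.start == len(BG) + 1 and l.end == len(BG) + 12

    def test_mono_run_below_threshold_ignored(self):
        assert find_ssrs(BG + "A" * 9 + BG[::-1]) == []

    def test_dinucleotide_not_reported_as_mono(self):
        loci = find_ssrs(BG + "AT" * 5 + BG[::-1])
        assert [(l.motif, l.unit_len, l.copies) for l in loci] == [("AT", 2, 5)]

    def test_primitivity_mono_never_counted_as_di(self):
        loci = find_ssrs("A" * 20)
        assert [(l.motif, l.copies) for l in loci] == [("A", 20)]

    def test_partial_trailing_copy_trimmed(self):
        seq = BG + "ACG" * 4 + "AC" + "TTGG"
        loci = find_ssrs(seq)
        (l,) = loci
        assert l.copies == 4
        assert l.end - l.start + 1 == 12
        assert seq[l.start - 1 : l.end] == "ACG" * 4

    def test_empty_sequence(self):
        assert find_ssrs("") == []

    def test_reported_span_reproduces_source_exactly(self):
        seq = BG + "AAG" * 6 + BG[::-1] + "GT" * 7 + BG
        for l in find_ssrs(seq):
            assert seq[l.start - 1 : l.end] == l.motif * l.copies

    def test_reverse_complement_symmetry(self):
        genome, truth = synth_genome(
            planted_ssrs=[SSRPlant("A", 12), SSRPlant("AG", 6), SSRPlant("ACT", 5)],
            seed=9,
            length=8000,
            n_genes=3,
        )
        fwd = find_ssrs(genome.seq)
        rev = find_ssrs(reverse_complement(genome.seq))
        assert len(fwd) == len(rev)
        n = len(genome.seq)
        mirrored = sorted((n - l.end + 1, n - l.start + 1) for l in fwd)
        assert mirrored == sorted((l.start, l.end) for l in rev)

    def test_same_motif_loci_never_overlap(self):
        genome, _ = synth_genome(
            planted_ssrs=[SSRPlant("A", 12), SSRPlant("A", 15)],
            seed=2,
            length=8000,
            n_genes=3,
        )
        loci = find_ssrs(genome.seq)
        by_motif: dict[str, list[SSRLocus]] = {}
        for l in loci:
            by_motif.setdefault(l.motif, []).append(l)
        for group in by_motif.values():
            group.sort(key=lambda l: l.start)
            for a, b in zip(group, group[1:]):
                assert a.end < b.start


class TestClassifySsrRegions:
    def test_region_classes_follow_annotation(self):
        genome, truth = synth_genome(
            planted_ssrs=[
                SSRPlant("A", 11, region="CDS"),
                SSRPlant("CT", 6, region="intron"),
                SSRPlant("AAG", 5, region="IGS"),
            ],
            seed=4,
            length=12000,
            n_genes=6,
        )
        loci = classify_ssr_regions(find_ssrs(genome.seq), genome)
        got = {(l.motif, l.region_class) for l in loci}
        assert got == {("A", "CDS"), ("CT", "intron"), ("AAG", "IGS")}


class TestFindTandemRepeats:
    def test_exact_triplet_recovered_with_full_identity(self):
        genome, truth = synth_genome(
            planted_tandems=[TandemPlant(40, 3)], seed=5, length=8000, n_genes=3
        )
        (t,) = find_tandem_repeats(genome.seq)
        (want,) = truth["tandems"]
        assert (t.unit_len, t.start, t.end) == (
            want["unit_len"],
            want["start"],
            want["end"],
        )
        assert t.identity == 1.0
        assert t.copies == 3

    def test_identity_floor_excludes_degraded_pair(self):
        # 6 substitutions in the second of two 40 bp copies -> identity 0.85
        genome, _ = synth_genome(
            planted_tandems=[TandemPlant(40, 2, substitutions=6)],
            seed=6,
            length=8000,
            n_genes=3,
        )
        assert find_tandem_repeats(genome.seq, min_identity=0.90) == []

    def test_planted_arrays_recovered_at_exact_coordinates(self):
        genome, truth = synth_genome(
            planted_tandems=[
                TandemPlant(40, 3),
                TandemPlant(32, 2),
                TandemPlant(55, 4, substitutions=2),
            ],
            seed=7,
            length=15000,
            n_genes=3,
        )
        got = {
            (t.unit_len, t.start, t.end) for t in find_tandem_repeats(genome.seq)
        }
        want = {
            (t["unit_len"], t["start"], t["end"]) for t in truth["tandems"]
        }
        assert got == want

    def test_min_unit_validation(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_unit=0)

    def test_clean_background_yields_nothing(self):
        genome, _ = synth_genome(seed=8, length=8000, n_genes=3)
        assert find_tandem_repeats(genome.seq) == []
        assert find_ssrs(genome.seq) == []
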