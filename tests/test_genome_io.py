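import pytest

from plastrace.genome_io import (
    AnnotatedGenome,
    Feature,
    GenomeParseError,
    extract_feature_seq,
    format_percent,
    gc_content,
    gene_order,
    hamming_diff,
    parse_genbank,
    reverse_complement,
    write_genbank,
)


class TestParseGenbank:
    def test_two_gene_record(self, two_gene_genbank):
        g = parse_genbank(two_gene_genbank)
        assert len(g) == 200
        assert g.circular
        genes = g.features_of_kind("gene")
        assert {f.name for f in genes} == {"geneA", "geneB"}

    def test_join_location_yields_exons_and_intron(self, two_gene_genbank):
        g = parse_genbank(two_gene_genbank)
        exons = [f for f in g.features if f.kind == "tRNA"]
        assert [(f.start, f.end) for f in exons] == [(80, 100), (115, 150)]
        introns = g.features_of_kind("intron")
        assert [(f.start, f.end) for f in introns] == [(101, 114)]
        assert introns[0].name == "geneB"

    def test_malformed_record_raises(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("LOCUS garbage\nnot a genbank record\n")
        with pytest.raises(GenomeParseError):
            parse_genbank(bad)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(GenomeParseError):
            AnnotatedGenome(id="x", seq="ACGRT")

    def test_round_trip_preserves_sequence_and_features(
        self, two_gene_genbank, tmp_path
    ):
        g = parse_genbank(two_gene_genbank)
        out = tmp_path / "rt.gb"
        write_genbank(g, str(out))
        g2 = parse_genbank(out)
        assert g2.seq == g.seq
        assert set(g2.features) == set(g.features)

    def test_feature_table_columns(self, two_gene_genbank, tmp_path):
        from plastrace.genome_io import write_feature_table

        g = parse_genbank(two_gene_genbank)
        out = tmp_path / "features.tsv"
        write_feature_table(g, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "name\tkind\tstart\tend\tstrand"
        assert len(lines) == len(g.features) + 1


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("GCNN", 1.0)],
    )
    def test_simple_fractions(self, seq, expected):
        g = AnnotatedGenome(id="t", seq=seq)
        assert gc_content(g) == expected

    def test_region_and_reverse_complement_invariance(self, toy_genome):
        region = (3, 10)
        fwd = gc_content(toy_genome, region)
        rc = AnnotatedGenome(id="rc", seq=reverse_complement(toy_genome.seq))
        n = len(toy_genome)
        mirrored = (n - region[1] + 1, n - region[0] + 1)
        assert gc_content(rc, mirrored) == fwd

    def test_empty_region_errors(self, toy_genome):
        with pytest.raises(ValueError):
            gc_content(toy_genome, (5, 300))

    def test_format_percent_rounds_half_up(self):
        # 5/32 is exact in binary; 15.625 must round up, not to even
        assert format_percent(5 / 32) == "15.63"
        assert format_percent(0.5) == "50.00"


class TestExtractFeatureSeq:
    def test_plus_strand(self, toy_genome):
        f = Feature("gene", "x", 1, 4, "+")
        assert extract_feature_seq(toy_genome, f) == "ACGT"

    def test_minus_strand_palindrome_identity(self, toy_genome):
        f = Feature("gene", "x", 1, 4, "-")
        assert extract_feature_seq(toy_genome, f) == "ACGT"  # rc of ACGT

    def test_minus_strand_general(self, toy_genome):
        f = Feature("gene", "x", 2, 5, "-")
        assert extract_feature_seq(toy_genome, f) == "TACG"

    def test_wrap_around_on_circular_genome(self, toy_genome):
        f = Feature("gene", "x", 18, 3, "+")
        assert extract_feature_seq(toy_genome, f) == "CGTACG"

    def test_unknown_feature_name_lists_available(self, toy_genome):
        with pytest.raises(KeyError, match="gA"):
            extract_feature_seq(toy_genome, "nonexistent")


class TestHammingDiff:
    def test_identical(self):
        assert hamming_diff("ACGT", "ACGT") == (0, [])

    def test_single_mismatch_position(self):
        assert hamming_diff("AAAA", "AATA") == (1, [3])

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="align"):
            hamming_diff("AAA", "AAAA")

    def test_symmetry_and_triangle_inequality(self):
        import random

        rng = random.Random(7)
        for _ in range(50):
            a, b, c = (
                "".join(rng.choice("ACGT") for _ in range(30)) for _ in range(3)
            )
            dab = hamming_diff(a, b)[0]
            assert dab == hamming_diff(b, a)[0]
            assert dab <= hamming_diff(a, c)[0] + hamming_diff(c, b)[0]


class TestGeneOrder:
    def _genome_from_order(self, signed):
        seq_parts = []
        features = []
        pos = 1
        for k, s in enumerate(signed):
            seq_parts.append("ACGTACGTAC")
            features.append(
                Feature(
                    "gene",
                    f"g{abs(s)}",
                    pos,
                    pos + 9,
                    "+" if s > 0 else "-",
                )
            )
            pos += 10
        return AnnotatedGenome(
            id="t", seq="".join(seq_parts), features=tuple(features)
        )

    def test_three_plus_strand_genes(self):
        g = self._genome_from_order([1, 2, 3])
        assert gene_order(g, ["g1", "g2", "g3"]).blocks == (1, 2, 3)

    def test_opposite_strand_reading_is_equivalent(self):
        from plastrace.rearrangement import SignedCircularPermutation

        g = self._genome_from_order([1, -3, 2])
        p = gene_order(g, ["g1", "g2", "g3"])
        flipped = SignedCircularPermutation(
            [-b for b in reversed(p.blocks)]
        )
        assert p == flipped  # reflection symmetry under canonicalization

    def test_round_trip_with_synthetic_order(self):
        from plastrace.synthetic_data import random_permutation

        p = random_permutation(8, seed=11)
        g = self._genome_from_order(p.blocks)
        got = gene_order(g, [f"g{k}" for k in range(1, 9)])
        assert got == p

    def test_missing_gene_errors(self, toy_genome):
        with pytest.raises(KeyError):
            gene_order(toy_genome, ["gA", "nope"])

    def test_duplicate_gene_errors(self):
        g = AnnotatedGenome(
            id="t",
            seq="ACGT" * 10,
            features=(
                Feature("gene", "dup", 1, 4, "+"),
                Feature("gene", "dup", 9, 12, "+"),
            ),
        )
        with pytest.raises(ValueError, match="disambiguate"):
            gene_order(g, ["dup"])
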