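import textwrap

import pytest

from plastrace.genome_io import AnnotatedGenome, Feature


@pytest.fixture
def two_gene_genbank(tmp_path):
    """A minimal synthetic GenBank record with two genes, one multi-exon."""
    seq = ("acgtacgtac" * 20)[:200]
    text = textwrap.dedent(
        f"""\
        LOCUS       SYNTH1                   200 bp    DNA     circular PLN 01-JAN-2000
        DEFINITION  synthetic two-gene test record.
        ACCESSION   SYNTH1
        FEATURES             Location/Qualifiers
             gene            10..60
                             /gene="geneA"
             CDS             10..60
                             /gene="geneA"
             gene            complement(80..150)
                             /gene="geneB"
             tRNA            join(80..100,115..150)
                             /gene="geneB"
        ORIGIN
        """
    )
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        text += f"{i + 1:>9} {grouped}\n"
    text += "//\n"
    path = tmp_path / "two_gene.gb"
    path.write_text(text)
    return path


@pytest.fixture
def toy_genome():
    """A hand-built annotated genome for coordinate-level assertions."""
    return AnnotatedGenome(
        id="toy",
        seq="ACGTACGTACGTACGTACGT",
        circular=True,
        features=(
            Feature("gene", "gA", 1, 4, "+"),
            Feature("gene", "gB", 9, 12, "-"),
        ),
    )
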