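"""Genome statistics: length, GC content and the gene-order permutation.

Builds a small synthetic annotated plastome, prints its Table-1-style
composition statistics, and reads off the signed gene order that the
rearrangement stage consumes.
"""

from plastrace import gc_content, gene_order
from plastrace.genome_io import format_percent
from plastrace.synthetic_data import synth_genome

genome, _ = synth_genome(n_genes=6, seed=1, length=15000)

print(f"genome {genome.id}: {len(genome)} bp, circular={genome.circular}")
print(f"GC content: {format_percent(gc_content(genome))}%")
# per-class GC, the way plastome tables report it
for kind in ("CDS", "intron"):
    feats = genome.features_of_kind(kind)
    gc = [gc_content(genome, (f.start, f.end)) for f in feats]
    mean = sum(gc) / len(gc)
    print(f"  {kind}: {len(feats)} features, mean GC {format_percent(mean)}%")

order = gene_order(genome, [f"gene{i}" for i in range(1, 7)])
print(f"signed gene order: {order}")
print(
    "The GC figures mirror plastome composition tables; the signed order "
    "is the input to the rearrangement analysis."
)
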