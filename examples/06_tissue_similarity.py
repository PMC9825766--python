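"""Gene-overlap similarity between tissues and top-k pretraining selection.

Each tissue's gene set is the nearest gene (by TSS distance from the anchor
midpoint) of every anchor in its positive interactions; similarity is the
proportion of shared genes among all genes of both tissues.
"""

from loopnet.interactions import build_labeled_dataset
from loopnet.similarity import GeneAnnotation, similarity_matrix, tissue_gene_set, top_k_similar
from loopnet.simulate import SimulationConfig, generate_genome, generate_tissue_interactions, write_genes_bed

cfg = SimulationConfig(n_chroms=2, chrom_len=1_200_000, n_genes_per_chrom=40,
                       tissues=tuple(f"T{i}" for i in range(7)), n_positives=60, seed=13)
genome, genes = generate_genome(cfg)
write_genes_bed(genes, "/tmp/loopnet_genes.bed")
annotation = GeneAnnotation.from_bed("/tmp/loopnet_genes.bed")

gene_sets = {}
for tissue in cfg.tissues:
    td = generate_tissue_interactions(cfg, genome, tissue)
    dataset = build_labeled_dataset(td.interactions, genome, seed=1)
    gene_sets[tissue] = tissue_gene_set([d for d in dataset if d.label == 1], annotation)
    print(f"{tissue}: {len(gene_sets[tissue])} nearest genes")

matrix = similarity_matrix(gene_sets)
print(matrix.round(3).to_string())
print("top-5 pretraining tissues for T0:", top_k_similar(matrix, "T0", k=5))
# Entries are Jaccard overlaps in [0, 1]; the diagonal is 1. The top-k list
# feeds select_pretraining_tissues(mode='top-k') for the shared paradigms.
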