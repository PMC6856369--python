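"""Detect syntenic blocks between two simulated genomes.

Two genomes descend from a 5-chromosome ancestor; one lineage fused two
chromosomes and inverted a segment.  Homolog pairs are chained on the
gene-rank dot plot into collinear blocks, and the chromosome
correspondence table summarises which counterpart chromosome(s) each
reference chromosome maps to.
"""

from protokaryo.annotation import HomologPair
from protokaryo.simulate import KaryotypeSimConfig, LineageSpec, simulate_karyotype_evolution
from protokaryo.synteny import ChainParams, block_summary, chromosome_correspondence, detect_collinear_blocks

cfg = KaryotypeSimConfig(
    n_proto=5, genes_per_proto=120,
    lineages={"ref": LineageSpec(),
              "other": LineageSpec(n_fusion=1, n_inversion=1)},
)
sim = simulate_karyotype_evolution(cfg, seed=17)

# pair keys are alphabetical; orient them with the reference first
pairs = [HomologPair(p.gene_b, p.gene_a, p.score, p.evalue)
         for p in sim.pairs[("other", "ref")]]
blocks = detect_collinear_blocks(
    pairs, sim.annotations["ref"], sim.annotations["other"], ChainParams(),
)
print(block_summary(blocks).to_string(index=False))
print()
for corr in chromosome_correspondence(blocks, "ref", "other"):
    for row in corr.rows:
        print(f"{corr.ref_chrom} -> {row.counterpart_chrom}: "
              f"{row.anchored_fraction:.2f} of anchors, patches {row.patches}")
# Each block is one diagonal of the dot plot ('-' = inverted segment).
# A reference chromosome split across two counterparts reflects the
# fusion on the other lineage; fractions say how much went where.
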