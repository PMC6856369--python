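"""Infer the ancestral chromosome complement of five simulated genomes.

An ancestor with 15 proto-chromosomes evolves along five lineages
(fusions, fissions, inversions; one lineage with a WGD).  Syntenic
blocks against the slowest (reference) genome feed the three
proto-chromosome rules, and the fusion/fission scenario is counted per
lineage.
"""

from protokaryo.annotation import HomologPair
from protokaryo.karyotype import infer_proto_chromosomes, reconstruct_scenario
from protokaryo.simulate import KaryotypeSimConfig, LineageSpec, simulate_karyotype_evolution
from protokaryo.synteny import ChainParams, detect_collinear_blocks

cfg = KaryotypeSimConfig(
    n_proto=15, genes_per_proto=200,
    lineages={
        "Bhi": LineageSpec(n_fusion=1, n_fission=1),
        "Cme": LineageSpec(n_fusion=2, n_inversion=2),
        "Cla": LineageSpec(n_fission=2, n_inversion=1),
        "Csa": LineageSpec(n_fusion=3, n_fission=2),
        "Cma": LineageSpec(n_fusion=2, wgd=True),
    },
)
sim = simulate_karyotype_evolution(cfg, seed=5)

ref = "Bhi"
blocks = {}
for other in sim.annotations:
    if other == ref:
        continue
    key = (min(ref, other), max(ref, other))
    pairs = sim.pairs[key]
    if key[0] != ref:
        pairs = [HomologPair(p.gene_b, p.gene_a, p.score, p.evalue) for p in pairs]
    blocks[other] = detect_collinear_blocks(pairs, sim.annotations[ref],
                                            sim.annotations[other], ChainParams())

result = infer_proto_chromosomes(blocks, sim.annotations, ref, wgd_genomes={"Cma"})
print(f"inferred proto-chromosomes: {result.n_protos} (simulated: 15)")
from collections import Counter

tally = Counter(result.classifications.values())
print(f"reference chromosome classes: {dict(tally)}")
# "preserved" demands a reciprocal one-to-one image in EVERY counterpart
# genome, so with five rearranged counterparts few chromosomes qualify;
# proto inference itself votes per junction and is far more tolerant.

scenario = reconstruct_scenario(result, sim.annotations)
for genome, ev in scenario.events.items():
    print(f"{genome}: {ev['fusion']} fusions, {ev['fission']} fissions, "
          f"WGD={ev['wgd']}")
# 'preserved' chromosomes are intact protos (rule A); 'partite' ones
# were fused on the reference lineage (rule B splits them); linked
# patches re-join protos the reference lineage fissioned (rule C).
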