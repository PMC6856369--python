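import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from protokaryo.annotation import HomologPair
from protokaryo.karyotype import KaryotypeParams, infer_proto_chromosomes
from protokaryo.simulate import (
    KaryotypeSimConfig,
    LineageSpec,
    simulate_karyotype_evolution,
)
from protokaryo.synteny import ChainParams, detect_collinear_blocks


def random_lineages(seed, names=("Bhi", "Cme", "Cla", "Csa", "Cma"),
                    wgd_name="Cma", ev_lo=3, ev_hi=8):
    """Draw per-lineage event counts for a recovery experiment."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for name in names:
        n_events = int(rng.integers(ev_lo, ev_hi + 1))
        mix = rng.multinomial(n_events, [0.35, 0.35, 0.3])
        lineages[name] = LineageSpec(
            n_fusion=int(mix[0]), n_fission=int(mix[1]), n_inversion=int(mix[2]),
            wgd=(name == wgd_name),
        )
    return lineages


def blocks_vs_reference(sim, ref, params=None):
    """Syntenic blocks of every counterpart genome against the reference."""
    params = params or ChainParams()
    out = {}
    for other in sim.annotations:
        if other == ref:
            continue
        key = (min(ref, other), max(ref, other))
        pairs = sim.pairs[key]
        if key[0] != ref:
            pairs = [HomologPair(p.gene_b, p.gene_a, p.score, p.evalue) for p in pairs]
        out[other] = detect_collinear_blocks(
            pairs, sim.annotations[ref], sim.annotations[other], params
        )
    return out


def karyotype_accuracy(sim, result):
    """(proto-count correct?, gene assignment accuracy) vs simulation truth.

    Inferred proto labels are matched to true protos by maximum-overlap
    assignment; unassigned genes count as errors.
    """
    from scipy.optimize import linear_sum_assignment

    true_ids = sorted({p for d in sim.truth.true_proto.values() for p in d.values()})
    inf_ids = sorted({p.proto_id for p in result.protos})
    M = np.zeros((len(true_ids), len(inf_ids)))
    ti = {p: i for i, p in enumerate(true_ids)}
    ii = {p: i for i, p in enumerate(inf_ids)}
    total = 0
    for genome, d in sim.truth.true_proto.items():
        assigned = result.assignment.get(genome, {})
        for gid, tp in d.items():
            total += 1
            ip = assigned.get(gid)
            if ip is not None:
                M[ti[tp], ii[ip]] += 1
    r, c = linear_sum_assignment(-M)
    return len(inf_ids) == len(true_ids), float(M[r, c].sum() / total)


def run_karyotype_recovery(seed, n_proto=15, genes_per_proto=200):
    """One full simulate -> blocks -> infer round; returns (sim, result)."""
    lineages = random_lineages(seed + 500)
    cfg = KaryotypeSimConfig(n_proto=n_proto, genes_per_proto=genes_per_proto,
                             lineages=lineages)
    sim = simulate_karyotype_evolution(cfg, seed)
    bbg = blocks_vs_reference(sim, "Bhi")
    res = infer_proto_chromosomes(bbg, sim.annotations, "Bhi", wgd_genomes={"Cma"},
                                  params=KaryotypeParams())
    return sim, res


@pytest.fixture(scope="session")
def karyotype_run():
    """A single cached recovery run shared by karyotype tests."""
    return run_karyotype_recovery(0)
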