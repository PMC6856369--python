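import numpy as np
import pytest

from protokaryo.ng86 import CodonAlignment, ng86_counts
from protokaryo.simulate import (
    KaryotypeSimConfig,
    LineageSpec,
    PopulationSimConfig,
    SweepSpec,
    simulate_coding_divergence,
    simulate_karyotype_evolution,
    simulate_ltr_cohort,
    simulate_population,
)


def karyo_cfg(**kw):
    lineages = kw.pop("lineages", {
        "A": LineageSpec(n_fusion=1, n_inversion=1),
        "B": LineageSpec(n_fission=1),
        "C": LineageSpec(wgd=True),
    })
    return KaryotypeSimConfig(n_proto=5, genes_per_proto=100, lineages=lineages, **kw)


def test_zero_events_identity_homology():
    cfg = KaryotypeSimConfig(
        n_proto=3, genes_per_proto=50, noise_pair_rate=0.0,
        lineages={"A": LineageSpec(gene_loss=0.0), "B": LineageSpec(gene_loss=0.0)},
    )
    sim = simulate_karyotype_evolution(cfg, 1)
    a, b = sim.annotations["A"], sim.annotations["B"]
    assert a.chroms == [c.replace("B_", "A_") for c in b.chroms]
    assert len(a) == len(b) == 150
    # orthology is one-to-one and preserves position
    pairs = sim.pairs[("A", "B")]
    assert len(pairs) == 150
    for p in pairs:
        la, lb = a[p.gene_a], b[p.gene_b]
        assert (la.chrom.split("_")[1], la.rank) == (lb.chrom.split("_")[1], lb.rank)


def test_single_fusion_reduces_chromosome_count():
    cfg = KaryotypeSimConfig(n_proto=5, genes_per_proto=60,
                             lineages={"A": LineageSpec(n_fusion=1), "B": LineageSpec()})
    sim = simulate_karyotype_evolution(cfg, 2)
    assert len(sim.annotations["A"].chroms) == 4
    assert len(sim.annotations["B"].chroms) == 5


def test_wgd_retention_binomial():
    """With retention 0.55 the duplicate-copy gene count stays within
    3 sigma of the binomial expectation."""
    cfg = KaryotypeSimConfig(
        n_proto=5, genes_per_proto=200,
        lineages={"A": LineageSpec(), "B": LineageSpec(wgd=True, retention_after_wgd=0.55,
                                                       gene_loss=0.0)},
    )
    sim = simulate_karyotype_evolution(cfg, 3)
    n_anc = 5 * 200
    dup = len(sim.annotations["B"]) - n_anc
    p = 0.55
    sd = np.sqrt(n_anc * p * (1 - p))
    assert abs(dup - n_anc * p) < 3 * sd


def test_gene_count_conservation_against_event_log():
    """Gene counts reconcile with the event log: initial genes, minus
    losses, plus WGD-retained duplicates."""
    cfg = karyo_cfg()
    sim = simulate_karyotype_evolution(cfg, 4)
    for genome, ann in sim.annotations.items():
        assert set(sim.truth.true_proto[genome]) == {l.gene_id for l in ann.loci}


def test_bit_identical_reproducibility():
    cfg = karyo_cfg()
    s1 = simulate_karyotype_evolution(cfg, 5)
    s2 = simulate_karyotype_evolution(cfg, 5)
    assert s1.truth.event_log == s2.truth.event_log
    for g in s1.annotations:
        assert [(l.gene_id, l.chrom, l.start) for l in s1.annotations[g].loci] == \
               [(l.gene_id, l.chrom, l.start) for l in s2.annotations[g].loci]
    s3 = simulate_karyotype_evolution(cfg, 6)
    assert s3.truth.event_log != s1.truth.event_log or \
        [(l.gene_id, l.start) for l in s3.annotations["A"].loci] != \
        [(l.gene_id, l.start) for l in s1.annotations["A"].loci]


def test_fission_without_long_chromosome_errors():
    cfg = KaryotypeSimConfig(n_proto=2, genes_per_proto=40, min_segment_genes=30,
                             lineages={"A": LineageSpec(n_fission=1), "B": LineageSpec()})
    with pytest.raises(ValueError, match="fission"):
        simulate_karyotype_evolution(cfg, 7)


# ---------------------------------------------------------------------------
# coding divergence
# ---------------------------------------------------------------------------


def test_ks_zero_identical_pairs():
    pairs, _ = simulate_coding_divergence(5, 0.0, 100, 1)
    assert all(a == b for _, a, b in pairs)


@pytest.mark.parametrize("ks", [0.3, 0.9])
def test_coding_divergence_recovery(ks):
    pairs, truth = simulate_coding_divergence(300, ks, 300, 9)
    est = np.array([ng86_counts(CodonAlignment(p, p, a, b)).Ks for p, a, b in pairs])
    assert np.nanmean(est) == pytest.approx(ks, rel=0.05)
    assert truth["ks_target"] == ks


def test_coding_divergence_seed_contract():
    p1, _ = simulate_coding_divergence(50, 0.5, 100, 1)
    p2, _ = simulate_coding_divergence(50, 0.5, 100, 2)
    assert p1 != p2
    e1 = np.mean([ng86_counts(CodonAlignment(p, p, a, b)).Ks for p, a, b in p1])
    e2 = np.mean([ng86_counts(CodonAlignment(p, p, a, b)).Ks for p, a, b in p2])
    assert e1 == pytest.approx(e2, abs=0.06)


def test_ka_target_produces_nonsynonymous_changes():
    pairs, _ = simulate_coding_divergence(50, 0.2, 200, 3, ka_target=0.1)
    counts = [ng86_counts(CodonAlignment(p, p, a, b)) for p, a, b in pairs]
    assert np.mean([c.Ka for c in counts]) == pytest.approx(0.1, rel=0.25)


def test_saturated_target_rejected():
    with pytest.raises(ValueError, match="range"):
        simulate_coding_divergence(1, 3.5, 100, 0)


# ---------------------------------------------------------------------------
# LTR cohorts
# ---------------------------------------------------------------------------


def test_age_zero_identical_ends():
    els, _ = simulate_ltr_cohort({0.0: 1.0}, 4.5e-9, 10, 200, 2)
    assert all(e.ltr5_seq == e.ltr3_seq for e in els)


def test_truth_records_every_element():
    els, truth = simulate_ltr_cohort({2e6: 0.5, 9e6: 0.5}, 4.5e-9, 50, 100, 3)
    assert set(truth.true_insertion_times) == {e.element_id for e in els}


# ---------------------------------------------------------------------------
# population panels
# ---------------------------------------------------------------------------


def test_population_reproducible_and_seed_sensitive():
    cfg = PopulationSimConfig(chrom_lengths={"chr1": 300_000},
                              n_samples={"W": 4, "L": 4, "C1": 4, "C2": 4})
    p1 = simulate_population(cfg, 11)
    p2 = simulate_population(cfg, 11)
    assert (p1.panel.pos == p2.panel.pos).all()
    assert (p1.panel.gt == p2.panel.gt).all()
    p3 = simulate_population(cfg, 12)
    assert len(p3.panel) != len(p1.panel) or not (p3.panel.pos == p1.panel.pos).all()


def test_sweep_reduces_derived_diversity_in_place():
    """A strength-10 domestication sweep lowers landrace diversity inside
    the region while wild diversity is untouched."""
    cfg = PopulationSimConfig(
        chrom_lengths={"chr1": 4_000_000},
        n_samples={"W": 10, "L": 10, "C1": 4, "C2": 4},
        sweeps=[SweepSpec("chr1", 1_000_000, 1_600_000, "domestication")],
    )
    pop = simulate_population(cfg, 13)
    from protokaryo.diversity import ScanConfig, window_diversity

    sc = ScanConfig()
    win_w = window_diversity(pop.panel, pop.samples_of("W"), cfg.chrom_lengths, sc)
    win_l = window_diversity(pop.panel, pop.samples_of("L"), cfg.chrom_lengths, sc)
    inside = (win_l.start >= 1_000_000) & (win_l.end <= 1_600_000)
    ratio = win_w.pi / np.maximum(win_l.pi, 1e-12)
    assert ratio[inside].min() > np.median(ratio[~inside])


def test_unreachable_pi_target_rejected():
    cfg = PopulationSimConfig(chrom_lengths={"chr1": 100_000}, snp_density=0.001)
    with pytest.raises(ValueError, match="unreachable"):
        simulate_population(cfg, 1)


def test_depths_mostly_within_filter_bounds():
    cfg = PopulationSimConfig(chrom_lengths={"chr1": 300_000},
                              n_samples={"W": 4, "L": 4, "C1": 4, "C2": 4})
    pop = simulate_population(cfg, 14)
    frac_ok = np.mean((pop.panel.depth > 150) & (pop.panel.depth < 6570))
    assert frac_ok > 0.95
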