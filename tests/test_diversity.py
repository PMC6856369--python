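import itertools

import numpy as np
import pytest

from protokaryo.diversity import (
    ScanConfig,
    hudson_fst_windows,
    tajimas_d,
    window_diversity,
)
from protokaryo.simulate import PopulationSimConfig, simulate_population
from protokaryo.variants import HET, HOM_ALT, HOM_REF, MISSING, VariantPanel, VariantSite


def panel_from_gt(gt, positions, chrom="c1"):
    gt = np.asarray(gt, dtype=np.int8)
    samples = [f"s{i}" for i in range(gt.shape[1])]
    sites = [
        VariantSite(chrom, int(p), "A", ("G",), gt[i], 1000)
        for i, p in enumerate(positions)
    ]
    return VariantPanel.from_sites(sites, samples), samples


# ---------------------------------------------------------------------------
# brute-force oracle over explicit allele copies
# ---------------------------------------------------------------------------


def oracle_stats(gt, window_len):
    """pi, thetaW (per bp) and Tajima's D by explicit O(n^2) pairwise
    comparison of allele copies, written independently of the library."""
    gt = np.asarray(gt)
    pi_total = 0.0
    S = 0
    ns = []
    for site in gt:
        copies = []
        for g in site:
            if g == HOM_REF:
                copies += [0, 0]
            elif g == HET:
                copies += [0, 1]
            elif g == HOM_ALT:
                copies += [1, 1]
        m = len(copies)
        if m < 2:
            continue
        ns.append(m)
        diffs = sum(
            1 for i, j in itertools.combinations(range(m), 2) if copies[i] != copies[j]
        )
        pi_total += diffs / (m * (m - 1) / 2)
        if 0 < sum(copies) < m:
            S += 1
    n = int(round(float(np.median(ns))))
    a1 = sum(1.0 / i for i in range(1, n))
    theta_w = S / a1 / window_len if S else 0.0
    # Tajima's D constants, written out again from the standard formulas
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if S > 0:
        d = (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    else:
        d = float("nan")
    return pi_total / window_len, theta_w, d


def test_two_haplotypes_one_difference():
    """Two haploid-like samples differing at one site in a 100 bp window
    give pi = 0.01."""
    gt = [[HOM_REF, HOM_ALT]]
    panel, samples = panel_from_gt(gt, [50])
    win = window_diversity(panel, samples, {"c1": 100},
                           ScanConfig(window=100, step=100, min_snps=1))
    # two diploid hom samples = two distinct haplotypes duplicated
    m = 4
    expect = 2 * (2 * 2) / (m * (m - 1)) / 100
    assert win.pi.iloc[0] == pytest.approx(expect, abs=1e-15)


def test_window_statistics_match_bruteforce_oracle():
    """pi, thetaW, Tajima's D equal the O(n^2) allele-copy oracle to
    1e-10 on panels of <= 12 haplotype-equivalents and <= 50 sites."""
    rng = np.random.default_rng(17)
    for trial in range(5):
        n_samples = int(rng.integers(3, 7))  # 6-12 allele copies
        n_sites = int(rng.integers(5, 51))
        gt = rng.choice([HOM_REF, HET, HOM_ALT], size=(n_sites, n_samples),
                        p=[0.5, 0.2, 0.3])
        positions = np.sort(rng.choice(np.arange(1, 10_000), n_sites, replace=False))
        panel, samples = panel_from_gt(gt, positions)
        cfg = ScanConfig(window=10_000, step=10_000, min_snps=1)
        win = window_diversity(panel, samples, {"c1": 10_000}, cfg)
        pi_o, tw_o, d_o = oracle_stats(gt, 10_000)
        assert win.pi.iloc[0] == pytest.approx(pi_o, abs=1e-10)
        assert win.theta_w.iloc[0] == pytest.approx(tw_o, abs=1e-10)
        if np.isfinite(d_o) and win.n_snps.iloc[0] >= cfg.min_snps:
            assert win.tajima_d.iloc[0] == pytest.approx(d_o, abs=1e-10)


def test_empty_window_zero_diversity_no_d():
    gt = [[HOM_REF, HOM_REF]]
    panel, samples = panel_from_gt(gt, [5000])
    win = window_diversity(panel, samples, {"c1": 10_000},
                           ScanConfig(window=10_000, step=10_000))
    assert win.pi.iloc[0] == 0.0
    assert win.theta_w.iloc[0] == 0.0
    assert np.isnan(win.tajima_d.iloc[0])


def test_d_absent_below_min_snps():
    rng = np.random.default_rng(3)
    gt = rng.choice([HOM_REF, HOM_ALT], size=(5, 6))
    panel, samples = panel_from_gt(gt, [10, 20, 30, 40, 50])
    win = window_diversity(panel, samples, {"c1": 100},
                           ScanConfig(window=100, step=100, min_snps=10))
    assert np.isnan(win.tajima_d.iloc[0])


def test_group_needs_two_samples():
    panel, samples = panel_from_gt([[HOM_REF]], [10])
    with pytest.raises(ValueError, match="2 samples"):
        window_diversity(panel, samples[:1], {"c1": 100}, ScanConfig(window=100, step=100))


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


def test_fst_zero_for_identical_frequencies():
    # 20 samples per group with identical allele frequencies; the
    # finite-sample correction leaves only a small negative residual
    gt = np.array([[HOM_ALT] * 10 + [HOM_REF] * 10 + [HOM_ALT] * 10 + [HOM_REF] * 10] * 10)
    panel, samples = panel_from_gt(gt, list(range(10, 110, 10)))
    win = hudson_fst_windows(panel, samples[:20], samples[20:], {"c1": 200},
                             ScanConfig(window=200, step=200))
    assert win.score.iloc[0] == pytest.approx(0.0, abs=0.05)


def test_fst_one_for_fixed_differences():
    gt = np.array([[HOM_REF, HOM_REF, HOM_ALT, HOM_ALT]] * 10)
    panel, samples = panel_from_gt(gt, list(range(10, 110, 10)))
    win = hudson_fst_windows(panel, samples[:2], samples[2:], {"c1": 200},
                             ScanConfig(window=200, step=200))
    assert win.score.iloc[0] == pytest.approx(1.0)


def test_fst_matches_hand_computation():
    """Two SNPs, hand-evaluated Hudson estimator (ratio of sums)."""
    # group A = s0,s1 ; group B = s2,s3 (4 allele copies each)
    gt = np.array([
        [HOM_ALT, HET, HOM_REF, HOM_REF],   # p1 = 3/4, p2 = 0
        [HET, HOM_REF, HOM_ALT, HET],        # p1 = 1/4, p2 = 3/4
    ])
    panel, samples = panel_from_gt(gt, [10, 20])
    win = hudson_fst_windows(panel, samples[:2], samples[2:], {"c1": 100},
                             ScanConfig(window=100, step=100))

    def site(p1, p2, n1=4, n2=4):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return num, den

    n1, d1 = site(0.75, 0.0)
    n2, d2 = site(0.25, 0.75)
    assert win.score.iloc[0] == pytest.approx((n1 + n2) / (d1 + d2), abs=1e-12)


def test_overlapping_groups_rejected():
    panel, samples = panel_from_gt([[HOM_REF, HOM_ALT, HET]], [10])
    with pytest.raises(ValueError, match="disjoint"):
        hudson_fst_windows(panel, samples[:2], samples[1:], {"c1": 100},
                           ScanConfig(window=100, step=100))


def test_simulated_groups_reproduce_diversity_ordering():
    """With targets 5.9/1.1/0.4 x 1e-3 the windowed estimates satisfy
    W > L > C in at least 95% of windows."""
    cfg = PopulationSimConfig(chrom_lengths={"chr1": 6_000_000},
                              n_samples={"W": 13, "L": 16, "C1": 20, "C2": 20})
    pop = simulate_population(cfg, 33)
    sc = ScanConfig()
    wins = {
        g: window_diversity(pop.panel, pop.samples_of(g), cfg.chrom_lengths, sc)
        for g in ("W", "L", "C")
    }
    ordered = (wins["W"].pi > wins["L"].pi) & (wins["L"].pi > wins["C"].pi)
    assert ordered.mean() >= 0.95
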