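import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from protokaryo.diversity import ScanConfig, hudson_fst_windows, window_diversity
from protokaryo.simulate import PopulationSimConfig, SweepSpec, simulate_population
from protokaryo.sweeps import candidate_windows, merge_windows, sweep_scan


def window_frame(chrom_len, values, window=200_000, step=20_000, n_snps=50):
    rows = []
    starts = range(0, chrom_len - window + step, step)
    for s, v in zip(starts, values):
        rows.append(("chr1", s, s + window, v, n_snps))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi", "n_snps"])


def test_merge_within_gap():
    """Candidate windows 1.00-1.20 Mb and 1.35-1.55 Mb (gap 150 kb) merge
    into one region; with a 250 kb gap they stay separate."""
    merged = merge_windows([("c1", 1_000_000, 1_200_000), ("c1", 1_350_000, 1_550_000)],
                           merge_gap=200_000)
    assert [(c, s, e) for c, s, e, _ in merged] == [("c1", 1_000_000, 1_550_000)]
    split = merge_windows([("c1", 1_000_000, 1_200_000), ("c1", 1_450_000, 1_650_000)],
                          merge_gap=200_000)
    assert len(split) == 2


@given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 10)), min_size=1,
                max_size=12))
def test_merge_is_order_invariant_and_idempotent(raw):
    """Merging is associative on interval sets: any input order gives the
    same regions, and re-merging the result changes nothing."""
    windows = [("c1", 10_000 * s, 10_000 * (s + w)) for s, w in raw]
    ref = merge_windows(sorted(windows), 15_000)
    perm = merge_windows(list(reversed(windows)), 15_000)
    assert [(c, s, e) for c, s, e, _ in ref] == [(c, s, e) for c, s, e, _ in perm]
    again = merge_windows([(c, s, e) for c, s, e, _ in ref], 15_000)
    assert [(c, s, e) for c, s, e, _ in again] == [(c, s, e) for c, s, e, _ in ref]


def test_grid_mismatch_rejected():
    a = window_frame(1_000_000, np.ones(41))
    b = window_frame(800_000, np.ones(31))
    with pytest.raises(ValueError, match="grid"):
        candidate_windows(a, b, a.rename(columns={"pi": "score"}), ScanConfig())


def test_candidate_selection_thresholds():
    """Exactly the top-decile-ratio windows that also clear the median
    score survive."""
    n = 40  # 4/40 swept: the decile threshold falls between background and swept
    length = 200_000 + 39 * 20_000
    pi_a = np.full(n, 5e-3)
    pi_b = np.linspace(0.9e-3, 1.1e-3, n)  # distinct background ratios
    pi_b[[5, 6, 7, 20]] = 1e-5  # four swept windows -> extreme ratios
    scores = np.linspace(0.0, 0.2, n)
    scores[[5, 6, 20]] = 0.9
    scores[7] = -1.0  # swept but undifferentiated: removed by score filter
    a = window_frame(length, pi_a)
    b = window_frame(length, pi_b)
    s = window_frame(length, scores).rename(columns={"pi": "score"})
    cfg = ScanConfig(top_ratio_fraction=0.10, top_secondary_fraction=0.50)
    df = candidate_windows(a, b, s, cfg)
    assert set(df.index[df.candidate]) == {5, 6, 20}


def planted_panel(seed=51):
    cfg = PopulationSimConfig(
        chrom_lengths={"chr1": 12_000_000, "chr2": 12_000_000},
        n_samples={"W": 13, "L": 16, "C1": 20, "C2": 20},
        sweeps=[
            SweepSpec("chr1", 2_000_000, 2_600_000, "domestication"),
            SweepSpec("chr1", 6_000_000, 6_600_000, "domestication"),
            SweepSpec("chr1", 9_500_000, 10_100_000, "domestication"),
            SweepSpec("chr2", 3_000_000, 3_600_000, "domestication"),
            SweepSpec("chr2", 8_000_000, 8_600_000, "domestication"),
        ],
    )
    return cfg, simulate_population(cfg, seed)


def independent_threshold_script(win_a, win_b, scores, cfg):
    """From-scratch reapplication of the published thresholds, written
    against the plain window tables (no library calls)."""
    pi_a = win_a.pi.to_numpy()
    pi_b = win_b.pi.to_numpy()
    sc = scores.score.to_numpy()
    eligible = (win_a.n_snps.to_numpy() >= cfg.min_snps) & np.isfinite(sc)
    floor = np.percentile(pi_b[eligible & (pi_b > 0)], 1)
    ratio = pi_a / np.where(pi_b > floor, pi_b, floor)
    r_thr = np.quantile(ratio[eligible], 1 - cfg.top_ratio_fraction)
    s_thr = np.quantile(sc[eligible], 1 - cfg.top_secondary_fraction)
    cand = eligible & (ratio >= r_thr) & (sc >= s_thr)
    regions = []
    for chrom in sorted(set(win_a.chrom)):
        rows = win_a[cand & (win_a.chrom == chrom).to_numpy()]
        cur = None
        for _, r in rows.sort_values("start").iterrows():
            if cur is not None and r.start - cur[1] <= cfg.merge_gap:
                cur[1] = max(cur[1], r.end)
            else:
                if cur is not None:
                    regions.append((chrom, cur[0], cur[1]))
                cur = [r.start, r.end]
        if cur is not None:
            regions.append((chrom, cur[0], cur[1]))
    return regions


def test_planted_sweeps_recovered_and_match_independent_script():
    """>= 4 of 5 planted strength-10 sweeps are recovered, and the merged
    call set is identical to an independent threshold script."""
    cfg, pop = planted_panel()
    sc = ScanConfig()
    win_w = window_diversity(pop.panel, pop.samples_of("W"), cfg.chrom_lengths, sc)
    win_l = window_diversity(pop.panel, pop.samples_of("L"), cfg.chrom_lengths, sc)
    scores = hudson_fst_windows(pop.panel, pop.samples_of("W"), pop.samples_of("L"),
                                cfg.chrom_lengths, sc)
    regions = sweep_scan(win_w, win_l, scores, sc, "domestication")
    calls = [(r.chrom, r.start, r.end) for r in regions]
    expected = independent_threshold_script(win_w, win_l, scores, sc)
    assert calls == [(c, int(s), int(e)) for c, s, e in expected]
    recovered = 0
    for chrom, s, e, _stage in pop.truth.true_sweeps:
        if any(rc == chrom and rs < e and re_ > s for rc, rs, re_ in calls):
            recovered += 1
    assert recovered >= 4
    for r in regions:
        assert r.length >= sc.window
    # regions within the stage do not overlap
    for c in {r.chrom for r in regions}:
        spans = sorted((r.start, r.end) for r in regions if r.chrom == c)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_neutral_panels_candidate_fraction_bounded():
    """Without planted sweeps the scan calls at most the expected
    top-fraction product of windows (plus sampling noise) over 20 seeds."""
    cfg = PopulationSimConfig(chrom_lengths={"chr1": 4_000_000},
                              n_samples={"W": 13, "L": 16, "C1": 2, "C2": 2})
    sc = ScanConfig()
    fractions = []
    for seed in range(20):
        pop = simulate_population(cfg, 900 + seed)
        win_w = window_diversity(pop.panel, pop.samples_of("W"), cfg.chrom_lengths, sc)
        win_l = window_diversity(pop.panel, pop.samples_of("L"), cfg.chrom_lengths, sc)
        scores = hudson_fst_windows(pop.panel, pop.samples_of("W"),
                                    pop.samples_of("L"), cfg.chrom_lengths, sc)
        df = candidate_windows(win_w, win_l, scores, sc)
        fractions.append(df.candidate.sum() / df.eligible.sum())
    bound = sc.top_ratio_fraction * sc.top_secondary_fraction
    sigma = np.std(fractions, ddof=1)
    assert np.mean(fractions) <= bound + 3 * sigma + 1e-9


def test_scan_config_validation():
    with pytest.raises(ValueError, match="step"):
        ScanConfig(window=100, step=200)
    with pytest.raises(ValueError, match="fraction"):
        ScanConfig(top_ratio_fraction=0.0)
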