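"""Windowed nucleotide diversity, Watterson's theta and Tajima's D.

Per site, with c0/c1 called reference/alternate allele counts and
m = c0 + c1, pairwise diversity is pi_site = 2 c0 c1 / (m (m - 1)).
A sliding window (default 200 kb, step 20 kb) accumulates

  pi      = sum(pi_site) / window_length_bp
  thetaW  = S / (a1 * window_length_bp),  a1 = sum_{i<n} 1/i

with S the number of segregating sites and n the median number of
called allele copies across the window's sites (missingness varies per
site, so a single n must be chosen; the median is robust).  Tajima's D
uses the standard normalising constants and is left undefined for
windows with fewer than ``min_snps`` segregating sites, where its
variance blows up.

The per-bp denominator is the full window length — windows are assumed
fully callable; the invariant-site mask of a real callset can be
supplied as an accessible-length override per window if needed.

A windowed Hudson F_ST (ratio of averages) between two groups is
provided as the secondary differentiation score for sweep filtering;
it is *not* XP-CLR, and externally computed XP-CLR scores can be
dropped in instead (see :mod:`protokaryo.sweeps`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import VariantPanel


@dataclass
class ScanConfig:
    window: int = 200_000
    step: int = 20_000
    top_ratio_fraction: float = 0.10
    top_secondary_fraction: float = 0.50
    merge_gap: int = 200_000
    min_snps: int = 10
    maf_min: float = 0.05
    missing_max: float = 0.10

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must be <= window")
        for f in (self.top_ratio_fraction, self.top_secondary_fraction):
            if not (0 < f <= 1):
                raise ValueError("top fractions must lie in (0, 1]")


def _allele_counts(panel: VariantPanel, sample_idx: np.ndarray):
    gt = panel.gt[:, sample_idx]
    called = gt >= 0
    m = 2 * called.sum(axis=1)
    c1 = (gt == 1).sum(axis=1) + 2 * (gt == 2).sum(axis=1)
    c0 = m - c1
    return c0.astype(float), c1.astype(float), m.astype(float)


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else float("nan")


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from S segregating sites, summed pairwise diversity and
    sample size n (allele copies); nan when undefined."""
    if S <= 0 or n < 3:
        return float("nan")
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / np.sqrt(var)


def window_grid(chrom_length: int, window: int, step: int):
    """Half-open (start, end) windows covering [0, chrom_length)."""
    starts = np.arange(0, max(chrom_length - window, 0) + step, step)
    if len(starts) == 0:
        starts = np.array([0])
    out = []
    for s in starts:
        out.append((int(s), int(min(s + window, chrom_length))))
    return out


def window_diversity(
    panel: VariantPanel,
    group_samples: list[str],
    chrom_lengths: dict[str, int],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Sliding-window pi, thetaW and Tajima's D for one sample group.

    Returns one row per window: chrom, start, end (bp, half-open), pi,
    theta_w (per bp), tajima_d (nan below ``min_snps``), n_snps and the
    median number of called allele copies.  The last window of a
    chromosome may be truncated and is flagged.
    """
    cfg = cfg or ScanConfig()
    if len(group_samples) < 2:
        raise ValueError("a group needs at least 2 samples")
    idx = panel.sample_index(group_samples)
    c0, c1, m = _allele_counts(panel, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(m >= 2, 2.0 * c0 * c1 / (m * (m - 1.0)), 0.0)
    seg = (c0 > 0) & (c1 > 0)

    rows = []
    chroms = np.asarray(panel.chrom, dtype=str)
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        on = chroms == chrom
        pos = panel.pos[on]  # 1-based
        psite = pi_site[on]
        s_on = seg[on]
        m_on = m[on]
        order = np.argsort(pos)
        pos, psite, s_on, m_on = pos[order], psite[order], s_on[order], m_on[order]
        for start, end in window_grid(L, cfg.window, cfg.step):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            length = end - start
            pi_total = float(psite[lo:hi].sum())
            S = int(s_on[lo:hi].sum())
            if hi > lo:
                n_med = int(round(float(np.median(m_on[lo:hi][m_on[lo:hi] >= 2]))))\
                    if (m_on[lo:hi] >= 2).any() else 0
            else:
                n_med = 0
            d = tajimas_d(S, pi_total, n_med) if S >= cfg.min_snps else float("nan")
            rows.append((chrom, start, end, pi_total / length,
                         S / (_harmonic(n_med) * length) if n_med >= 2 and S > 0 else 0.0,
                         d, S, n_med, end - start < cfg.window))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pi", "theta_w", "tajima_d",
                       "n_snps", "n_alleles", "truncated"],
    )


def hudson_fst_windows(
    panel: VariantPanel,
    samples_a: list[str],
    samples_b: list[str],
    chrom_lengths: dict[str, int],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Windowed Hudson F_ST between two groups (ratio of averages).

    Per site, with sample frequencies p1, p2 and allele-copy counts
    n1, n2:  num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    den = p1(1-p2) + p2(1-p1); the window score is sum(num)/sum(den).
    Windows without usable SNPs get a NaN score.
    """
    cfg = cfg or ScanConfig()
    if set(samples_a) & set(samples_b):
        raise ValueError("groups share samples; F_ST requires disjoint groups")
    ia, ib = panel.sample_index(samples_a), panel.sample_index(samples_b)
    c0a, c1a, na = _allele_counts(panel, ia)
    c0b, c1b, nb = _allele_counts(panel, ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(na > 0, c1a / na, np.nan)
        p2 = np.where(nb > 0, c1b / nb, np.nan)
        num = (p1 - p2) ** 2 \
            - p1 * (1 - p1) / np.maximum(na - 1, 1) \
            - p2 * (1 - p2) / np.maximum(nb - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = np.isfinite(num) & np.isfinite(den) & (na >= 2) & (nb >= 2)

    rows = []
    chroms = np.asarray(panel.chrom, dtype=str)
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        on = chroms == chrom
        pos = panel.pos[on]
        nm, dn, us = num[on], den[on], usable[on]
        order = np.argsort(pos)
        pos, nm, dn, us = pos[order], nm[order], dn[order], us[order]
        for start, end in window_grid(L, cfg.window, cfg.step):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            sl = slice(lo, hi)
            w_us = us[sl]
            if w_us.sum() == 0 or dn[sl][w_us].sum() == 0:
                score = float("nan")
            else:
                score = float(nm[sl][w_us].sum() / dn[sl][w_us].sum())
            rows.append((chrom, start, end, score, int(w_us.sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_snps"])
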