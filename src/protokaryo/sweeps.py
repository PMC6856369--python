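"""Two-stage selective-sweep scan by windowed diversity ratio.

Domestication reduces diversity in the derived group, so windows where
pi(ancestral)/pi(derived) is extreme are sweep candidates.  The scan
takes two windowed diversity tables on the same grid (e.g. wild vs
landrace for the domestication stage, landrace vs cultivated for the
improvement stage), ranks windows by the diversity ratio, keeps the top
``top_ratio_fraction`` (default 10%), intersects them with the top
``top_secondary_fraction`` (default 50%) of a secondary differentiation
score, and merges surviving windows separated by at most ``merge_gap``
(default 200 kb) into regions.

The denominator pi is floored at its 1st percentile over non-zero
windows so that empty-window ratios do not become infinite — they rank
at the top, which is the intended behaviour for a hard sweep.  Windows
with fewer than ``min_snps`` SNPs in the *ancestral* group, or without
a secondary score, are reported but excluded from percentile ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .diversity import ScanConfig


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    stage: str  # domestication | improvement
    peak_ratio: float
    peak_secondary_score: float
    member_windows: list[tuple[int, int]] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ka = list(zip(a.chrom, a.start, a.end))
    kb = list(zip(b.chrom, b.start, b.end))
    if ka != kb:
        raise ValueError("window tables are not on an identical grid")


def candidate_windows(
    win_ancestral: pd.DataFrame,
    win_derived: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Per-window ratios, thresholds and candidate flags (pre-merge)."""
    cfg = cfg or ScanConfig()
    _check_same_grid(win_ancestral, win_derived)
    _check_same_grid(win_ancestral, scores)
    df = win_ancestral[["chrom", "start", "end", "pi", "n_snps"]].rename(
        columns={"pi": "pi_a", "n_snps": "n_snps_a"}
    ).copy()
    df["pi_b"] = win_derived["pi"].to_numpy()
    df["score"] = scores["score"].to_numpy()
    eligible = (df.n_snps_a >= cfg.min_snps) & np.isfinite(df.score)
    df["eligible"] = eligible

    nonzero_b = df.pi_b[eligible & (df.pi_b > 0)]
    floor = float(np.percentile(nonzero_b, 1)) if len(nonzero_b) else np.nan
    df["ratio"] = df.pi_a / np.maximum(df.pi_b, floor)
    df.loc[~eligible, "ratio"] = np.nan

    el = df[eligible]
    ratio_thr = float(np.quantile(el.ratio, 1.0 - cfg.top_ratio_fraction))
    score_thr = float(np.quantile(el.score, 1.0 - cfg.top_secondary_fraction))
    df["candidate"] = eligible & (df.ratio >= ratio_thr) & (df.score >= score_thr)
    df.attrs["ratio_threshold"] = ratio_thr
    df.attrs["score_threshold"] = score_thr
    df.attrs["pi_b_floor"] = floor
    return df


def merge_windows(
    windows: list[tuple[str, int, int]], merge_gap: int
) -> list[tuple[str, int, int, list[tuple[int, int]]]]:
    """Merge half-open windows whose gap is <= merge_gap (per chromosome).

    Returns (chrom, start, end, member_windows); associative and
    independent of input order.
    """
    out = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in windows:
        by_chrom.setdefault(c, []).append((s, e))
    for c in sorted(by_chrom):
        ws = sorted(by_chrom[c])
        cur_s, cur_e = ws[0]
        members = [ws[0]]
        for s, e in ws[1:]:
            if s - cur_e <= merge_gap:
                cur_e = max(cur_e, e)
                members.append((s, e))
            else:
                out.append((c, cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, [(s, e)]
        out.append((c, cur_s, cur_e, members))
    return out


def sweep_scan(
    win_ancestral: pd.DataFrame,
    win_derived: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: ScanConfig | None = None,
    stage_label: str = "domestication",
    annotation: GenomeAnnotation | None = None,
) -> list[SweepRegion]:
    """Run one stage of the sweep scan and return merged regions.

    ``scores`` may come from :func:`protokaryo.diversity.hudson_fst_windows`
    or from an external tool (e.g. XP-CLR) reformatted onto the same
    window grid.  If an annotation is given, genes overlapping each
    region are attached.
    """
    cfg = cfg or ScanConfig()
    df = candidate_windows(win_ancestral, win_derived, scores, cfg)
    cands = df[df.candidate]
    regions = []
    merged = merge_windows(
        [(str(r.chrom), int(r.start), int(r.end)) for r in cands.itertuples()],
        cfg.merge_gap,
    )
    for chrom, start, end, members in merged:
        sub = cands[(cands.chrom == chrom) & (cands.start >= start) & (cands.end <= end)]
        region = SweepRegion(
            chrom, start, end, stage_label,
            peak_ratio=float(sub.ratio.max()),
            peak_secondary_score=float(sub.score.max()),
            member_windows=members,
        )
        if annotation is not None:
            region.gene_ids = [
                g.gene_id for g in annotation.genes_on(chrom)
                if g.start < end and g.end > start
            ]
        regions.append(region)
    return regions


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.stage, r.peak_ratio, r.peak_secondary_score)
         for r in regions],
        columns=["chrom", "start", "end", "stage", "peak_ratio", "score"],
    )
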