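"""Variant panel container and hard-filtering of a resequencing panel.

Genotypes are stored as an (n_sites, n_samples) int8 matrix with codes
0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing — adequate for an
inbred diploid panel where per-site allele counts, not phase, drive
every downstream statistic.

The hard filter reproduces the standard resequencing criteria for a
selfing crop panel, applied in a fixed order so every dropped site is
attributed to its *first* failing criterion:

  (o)   InDels longer than 5 bp (SNP-only criteria do not apply);
  (i)   more than two alleles at the position;
  (ii)  total depth outside (150, 6570) — the upper bound screens
        collapsed repeats, the lower bound under-covered sites;
  (iii) another variant within 1 bp — both members of an adjacent pair
        are removed (symmetric and conservative);
  (iv)  fewer than 85% of called lines homozygous, or heterozygous
        calls exceeding three times the minor-allele homozygote count
        (residual-heterozygosity artefacts in an inbred panel).

Adjacency (iii) is evaluated against the *input* site list; because
both members of a close pair are dropped, filtering is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: tuple[str, ...]
    genotypes: np.ndarray  # int8 codes per sample
    total_depth: int
    variant_type: str = "SNP"  # SNP | InDel
    indel_len: int = 0

    @property
    def n_alt(self) -> int:
        return len(self.alt)


class VariantPanel:
    """Column-oriented container for a biallelic-ish variant panel."""

    def __init__(self, samples, chrom, pos, ref, alt, gt, depth,
                 variant_type=None, indel_len=None):
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = list(alt)  # list of tuples
        self.gt = np.asarray(gt, dtype=np.int8)
        self.depth = np.asarray(depth, dtype=np.int64)
        n = len(self.pos)
        self.variant_type = (
            np.asarray(variant_type, dtype=object)
            if variant_type is not None
            else np.array(["SNP"] * n, dtype=object)
        )
        self.indel_len = (
            np.asarray(indel_len, dtype=np.int64)
            if indel_len is not None
            else np.zeros(n, dtype=np.int64)
        )
        if self.gt.shape != (n, len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in panel") from None

    def subset(self, mask: np.ndarray) -> "VariantPanel":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return VariantPanel(
            self.samples, self.chrom[idx], self.pos[idx], self.ref[idx],
            [self.alt[i] for i in idx], self.gt[idx], self.depth[idx],
            self.variant_type[idx], self.indel_len[idx],
        )

    def sites(self) -> Iterator[VariantSite]:
        for i in range(len(self)):
            yield VariantSite(
                str(self.chrom[i]), int(self.pos[i]), str(self.ref[i]),
                tuple(self.alt[i]), self.gt[i], int(self.depth[i]),
                str(self.variant_type[i]), int(self.indel_len[i]),
            )

    @classmethod
    def from_sites(cls, sites: list[VariantSite], samples) -> "VariantPanel":
        return cls(
            samples,
            [s.chrom for s in sites],
            [s.pos for s in sites],
            [s.ref for s in sites],
            [s.alt for s in sites],
            np.array([s.genotypes for s in sites], dtype=np.int8).reshape(
                len(sites), len(samples)
            ),
            [s.total_depth for s in sites],
            [s.variant_type for s in sites],
            [s.indel_len for s in sites],
        )

    def is_sorted(self) -> bool:
        for i in range(1, len(self)):
            if self.chrom[i] == self.chrom[i - 1] and self.pos[i] < self.pos[i - 1]:
                return False
        return True


@dataclass
class FilterConfig:
    depth_min: int = 150      # exclusive lower bound
    depth_max: int = 6570     # exclusive upper bound
    adjacent_bp: int = 1      # drop variants with a neighbour <= this many bp away
    hom_fraction_min: float = 0.85
    het_hom_minor_ratio: float = 3.0
    indel_len_max: int = 5


@dataclass
class FilterReport:
    input_sites: int = 0
    retained: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {
        "indel_long": 0, "multiallelic": 0, "depth_low": 0, "depth_high": 0,
        "adjacent": 0, "low_hom_fraction": 0, "het_excess": 0,
    })

    def check_conservation(self) -> bool:
        return self.input_sites == self.retained + sum(self.drops.values())


def filter_variants(
    panel: VariantPanel, cfg: FilterConfig | None = None
) -> tuple[VariantPanel, FilterReport]:
    """Apply the hard filter; returns the retained panel and a drop report."""
    cfg = cfg or FilterConfig()
    if not panel.is_sorted():
        raise ValueError("variant panel must be sorted by (chrom, pos)")
    n = len(panel)
    report = FilterReport(input_sites=n)

    n_alt = np.array([len(a) for a in panel.alt])
    is_indel = panel.variant_type == "InDel"

    has_close = np.zeros(n, dtype=bool)
    order = np.lexsort((panel.pos, panel.chrom.astype(str)))
    sp = panel.pos[order]
    sc = panel.chrom.astype(str)[order]
    same = (sc[1:] == sc[:-1]) & (sp[1:] - sp[:-1] <= cfg.adjacent_bp)
    close_sorted = np.zeros(n, dtype=bool)
    close_sorted[:-1] |= same
    close_sorted[1:] |= same
    has_close[order] = close_sorted

    called = panel.gt >= 0
    n_called = called.sum(axis=1)
    n_het = (panel.gt == HET).sum(axis=1)
    n_hom_ref = (panel.gt == HOM_REF).sum(axis=1)
    n_hom_alt = (panel.gt == HOM_ALT).sum(axis=1)
    n_hom = n_hom_ref + n_hom_alt
    n_hom_minor = np.minimum(n_hom_ref, n_hom_alt)

    with np.errstate(invalid="ignore", divide="ignore"):
        hom_frac = np.where(n_called > 0, n_hom / np.maximum(n_called, 1), 0.0)

    conditions = [
        is_indel & (panel.indel_len > cfg.indel_len_max),
        n_alt > 1,
        panel.depth <= cfg.depth_min,
        panel.depth >= cfg.depth_max,
        has_close,
        (n_called == 0) | (hom_frac < cfg.hom_fraction_min),
        n_het > cfg.het_hom_minor_ratio * n_hom_minor,
    ]
    labels = ["indel_long", "multiallelic", "depth_low", "depth_high",
              "adjacent", "low_hom_fraction", "het_excess"]
    reason = np.select(conditions, labels, default="")

    keep = reason == ""
    for r in reason[~keep]:
        report.drops[r] += 1
    report.retained = int(keep.sum())
    return panel.subset(keep), report


# ---------------------------------------------------------------------------
# VCF I/O (plain-text VCF; reading via cyvcf2)
# ---------------------------------------------------------------------------


def write_vcf(panel: VariantPanel, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    gt_strings = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for c, L in sorted(chrom_lengths.items()):
                fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for i in range(len(panel)):
            alt = ",".join(panel.alt[i])
            gts = "\t".join(gt_strings[int(g)] for g in panel.gt[i])
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{panel.ref[i]}\t{alt}\t.\tPASS\t"
                f"DP={panel.depth[i]}\tGT\t{gts}\n"
            )


def load_vcf(path: str | Path) -> VariantPanel:
    """Read a (possibly gzipped) VCF into a panel via cyvcf2.

    Multi-allelic records are kept (genotype codes refer to the first
    ALT) so the hard filter can count and drop them itself.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, gts, depth, vtype, ilen = [], [], [], [], [], [], [], []
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(tuple(rec.ALT))
        g = rec.gt_types.astype(np.int8)  # 0=hom_ref,1=het,2=hom_alt,3=missing
        g[g == 3] = MISSING
        gts.append(g)
        dp = rec.INFO.get("DP")
        depth.append(int(dp) if dp is not None else 0)
        if rec.is_indel:
            vtype.append("InDel")
            ilen.append(max(abs(len(a) - len(rec.REF)) for a in rec.ALT) if rec.ALT else 0)
        else:
            vtype.append("SNP")
            ilen.append(0)
    return VariantPanel(samples, chrom, pos, ref, alt,
                        np.array(gts, dtype=np.int8).reshape(len(pos), len(samples)),
                        depth, vtype, ilen)
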