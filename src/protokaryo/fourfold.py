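"""Fourfold-degenerate site extraction and near-neutral SNP subsetting.

A fourfold-degenerate (4D) site is a codon third position at which any
of the four nucleotides encodes the same amino acid; SNPs restricted to
these positions are approximately neutral and are the standard marker
set for population-structure work in selfing crops.

Coordinates are mapped through multi-exon, mixed-strand gene models:
CDS segments are concatenated in transcription order (reverse-
complemented on the minus strand, leading ``phase`` bases trimmed) and
each 4D third position is projected back to its 1-based genomic
coordinate.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .variants import VariantPanel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _is_fourfold(codon: str, forward: dict, stops: set) -> bool:
    aas = set()
    for nt in "ACGT":
        c = codon[:2] + nt
        if c in stops:
            return False
        aas.add(forward[c])
    return len(aas) == 1


def fourfold_sites(
    gff_path: str | Path,
    genome_fasta: str | Path,
    table_id: int = 1,
) -> set[tuple[str, int]]:
    """Genomic positions (chrom, 1-based pos) of all 4D codon third positions.

    CDS features are grouped by parent transcript; transcripts whose
    concatenated CDS has an internal stop or a length not divisible by
    3 are skipped with a log message.
    """
    import gffutils
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = table.forward_table
    stops = set(table.stop_codons)

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True, force=True)
    out: set[tuple[str, int]] = set()
    cds_by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "orphan"])
        cds_by_parent.setdefault(parents[0], []).append(cds)

    for parent, segs in sorted(cds_by_parent.items()):
        strand = segs[0].strand
        chrom = segs[0].seqid
        segs = sorted(segs, key=lambda s: s.start, reverse=(strand == "-"))
        coords: list[int] = []  # genomic 1-based position of each CDS base, 5'->3'
        seq_parts: list[str] = []
        for s in segs:
            bases = genome[chrom][s.start - 1: s.end]
            positions = list(range(s.start, s.end + 1))
            if strand == "-":
                bases = bases.translate(_COMPLEMENT)[::-1]
                positions = positions[::-1]
            seq_parts.append(bases)
            coords.extend(positions)
        seq = "".join(seq_parts)
        phase = segs[0].frame
        trim = int(phase) if phase not in (None, ".", "") else 0
        seq = seq[trim:]
        coords = coords[trim:]
        usable = len(seq) - len(seq) % 3
        seq = seq[:usable]
        coords = coords[:usable]
        if not seq:
            continue
        aa = str(Seq(seq).translate(table=table_id))
        if "*" in aa[:-1]:
            logger.warning("transcript %s: internal stop codon; skipped", parent)
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i: i + 3]
            if set(codon) - set("ACGT"):
                continue
            if codon in stops:
                continue
            if _is_fourfold(codon, forward, stops):
                out.add((chrom, coords[i + 2]))
    return out


def subset_4d_snps(
    panel: VariantPanel,
    fourfold_set: set[tuple[str, int]],
    maf_min: float = 0.05,
    missing_max: float = 0.10,
) -> VariantPanel:
    """Restrict a filtered SNP panel to 4D positions with MAF > ``maf_min``
    among called alleles and missing-genotype fraction < ``missing_max``."""
    n = len(panel)
    keep = np.zeros(n, dtype=bool)
    called = panel.gt >= 0
    n_called = called.sum(axis=1)
    alt_count = (panel.gt == 1).sum(axis=1) + 2 * (panel.gt == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, alt_count / np.maximum(2 * n_called, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    missing = (panel.n_samples - n_called) / panel.n_samples
    for i in range(n):
        if (str(panel.chrom[i]), int(panel.pos[i])) not in fourfold_set:
            continue
        if panel.variant_type[i] != "SNP":
            continue
        keep[i] = (maf[i] > maf_min) and (missing[i] < missing_max)
    return panel.subset(keep)
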