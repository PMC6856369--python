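"""Gene annotations and homologous gene pairs.

Gene orders are the substrate of every downstream comparison: synteny
blocks are chained on *gene ranks* (the index of a gene along its
chromosome), not on base-pair coordinates, so the central job of this
module is to read an annotation (GFF3 or a simple gene BED/TSV), assign
ranks per chromosome and hand out :class:`GenomeAnnotation` objects.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class GeneLocus:
    """A single gene on a chromosome.

    ``rank`` is the 0-based index of the gene along its chromosome when
    genes are ordered by start coordinate; it is assigned by
    :meth:`GenomeAnnotation.from_loci` and is unique and consecutive
    within a chromosome.
    """

    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


class GenomeAnnotation:
    """Ordered gene coordinates of one genome."""

    def __init__(self, genome_id: str, loci: list[GeneLocus], chrom_lengths: dict[str, int]):
        self.genome_id = genome_id
        self.loci = loci
        self.chrom_lengths = dict(chrom_lengths)
        self._by_id = {l.gene_id: l for l in loci}
        if len(self._by_id) != len(loci):
            seen: set[str] = set()
            for l in loci:
                if l.gene_id in seen:
                    raise ValueError(f"duplicate gene ID {l.gene_id!r} in genome {genome_id!r}")
                seen.add(l.gene_id)
        self._by_chrom: dict[str, list[GeneLocus]] = {}
        for l in loci:
            self._by_chrom.setdefault(l.chrom, []).append(l)
        for chrom, cl in self._by_chrom.items():
            cl.sort(key=lambda l: l.rank)
            if chrom not in self.chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} missing from chrom_lengths")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_loci(
        cls,
        genome_id: str,
        loci: Iterable[GeneLocus],
        chrom_lengths: dict[str, int] | None = None,
    ) -> "GenomeAnnotation":
        """Build an annotation, assigning ranks by start position per chromosome."""
        by_chrom: dict[str, list[GeneLocus]] = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append(l)
        ranked: list[GeneLocus] = []
        for chrom in sorted(by_chrom):
            genes = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
            for i, l in enumerate(genes):
                ranked.append(GeneLocus(l.gene_id, l.chrom, l.start, l.end, l.strand, rank=i))
        if chrom_lengths is None:
            chrom_lengths = {c: max(l.end for l in ls) for c, ls in by_chrom.items()}
        return cls(genome_id, ranked, chrom_lengths)

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chrom: str) -> list[GeneLocus]:
        """Genes of one chromosome in rank order."""
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not found in genome {self.genome_id!r}") from None

    def n_genes(self, chrom: str) -> int:
        return len(self._by_chrom.get(chrom, []))


@dataclass(frozen=True)
class HomologPair:
    """A putative homologous gene pair (e.g. from an all-vs-all protein search)."""

    gene_a: str
    gene_b: str
    score: float = 0.0
    evalue: float = 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "gene_id", "strand"]


def load_annotation(path: str | Path, genome_id: str, fmt: str | None = None) -> GenomeAnnotation:
    """Read a gene annotation from GFF3 or a 5-column gene BED/TSV.

    GFF3 ``gene`` features (``ID`` attribute required) are used; 1-based
    inclusive GFF coordinates are converted to 0-based half-open.
    Duplicate gene IDs are rejected with the offending ID named.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if fmt == "gff3":
        loci = _read_gff3_genes(path)
        chrom_lengths = _read_gff3_regions(path)
    elif fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, comment="#")
        loci = [
            GeneLocus(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
            for r in df.itertuples()
        ]
        chrom_lengths = None
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    ann = GenomeAnnotation.from_loci(genome_id, loci, chrom_lengths)
    for chrom in ann.chrom_lengths:
        if ann.n_genes(chrom) == 0:
            warnings.warn(f"chromosome {chrom!r} declared but carries zero genes")
    return ann


def _read_gff3_genes(path: Path) -> list[GeneLocus]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True, force=True
    )
    loci = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen:
            raise ValueError(f"duplicate gene ID {gid!r} in {path}")
        seen.add(gid)
        loci.append(GeneLocus(gid, feat.seqid, feat.start - 1, feat.end, feat.strand or "+"))
    return loci


def _read_gff3_regions(path: Path) -> dict[str, int] | None:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                lengths[chrom] = int(end)
            elif not line.startswith("#"):
                break
    return lengths or None


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in ann.chroms:
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for chrom in ann.chroms:
            for l in ann.genes_on(chrom):
                fh.write(
                    f"{chrom}\tprotokaryo\tgene\t{l.start + 1}\t{l.end}\t.\t{l.strand}\t.\t"
                    f"ID={l.gene_id}\n"
                )


def write_bed(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in ann.chroms:
            for l in ann.genes_on(chrom):
                fh.write(f"{chrom}\t{l.start}\t{l.end}\t{l.gene_id}\t{l.strand}\n")


def load_homolog_pairs(
    path: str | Path, evalue_max: float = 1e-5
) -> list[HomologPair]:
    """Read homolog pairs from a TSV (gene_a, gene_b, score, evalue).

    Pairs above the e-value inclusion threshold (default 1e-5, the
    conventional cut-off for calling two proteins potential homologs)
    are discarded; self-pairs are dropped.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_a", "gene_b", "score", "evalue"], comment="#"
    )
    out = []
    for r in df.itertuples():
        if r.evalue > evalue_max or r.gene_a == r.gene_b:
            continue
        out.append(HomologPair(str(r.gene_a), str(r.gene_b), float(r.score), float(r.evalue)))
    return out


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:g}\t{p.evalue:g}\n")
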