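"""Collinear (syntenic) block detection on the gene-rank dot plot.

Homologous gene pairs between two annotated genomes define points
``(rank_a, rank_b)`` on a dot plot.  A syntenic block is a strictly
monotone chain of such anchors — increasing in both ranks (orientation
``+``) or increasing in ``rank_a`` while decreasing in ``rank_b``
(orientation ``-``) — with at most ``max_gap_genes`` skipped genes
between consecutive anchors on either axis.

Blocks are extracted greedily: the highest-scoring chain (score = anchor
count) is accepted, its anchors removed, and the search repeated until
no chain of at least ``min_anchors`` anchors remains.  Ties are broken
deterministically (lexicographically smallest anchor sequence, then
orientation ``+`` before ``-``) so the decomposition is reproducible and
can be checked against exhaustive enumeration on small inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, HomologPair


@dataclass
class ChainParams:
    min_anchors: int = 5
    max_gap_genes: int = 25


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchor pairs between two chromosomes."""

    block_id: str
    genome_a: str
    chrom_a: str
    genome_b: str
    chrom_b: str
    anchors: list[tuple[int, int, str, str]]  # (rank_a, rank_b, gene_a, gene_b)
    orientation: str  # '+' or '-'
    median_ks: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ra = [a[0] for a in self.anchors]
        return min(ra), max(ra)

    @property
    def span_b(self) -> tuple[int, int]:
        rb = [a[1] for a in self.anchors]
        return min(rb), max(rb)


# ---------------------------------------------------------------------------
# anchor preparation
# ---------------------------------------------------------------------------


def _resolve_anchors(
    pairs: list[HomologPair], ann_a: GenomeAnnotation, ann_b: GenomeAnnotation
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        if p.gene_a not in ann_a:
            raise KeyError(f"gene {p.gene_a!r} not found in genome {ann_a.genome_id!r}")
        if p.gene_b not in ann_b:
            raise KeyError(f"gene {p.gene_b!r} not found in genome {ann_b.genome_id!r}")
        la, lb = ann_a[p.gene_a], ann_b[p.gene_b]
        rows.append((la.chrom, la.rank, lb.chrom, lb.rank, p.gene_a, p.gene_b, p.score))
    return pd.DataFrame(
        rows, columns=["chrom_a", "rank_a", "chrom_b", "rank_b", "gene_a", "gene_b", "score"]
    )


def _collapse_tandem(df: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Collapse tandem-array redundancy.

    Among pairs sharing one gene whose partners sit within ``max_gap``
    ranks of each other on the same partner chromosome, only the
    best-scoring pair is kept.  This prevents local gene-family arrays
    from inflating a diagonal into a thick band.
    """

    def collapse_side(d: pd.DataFrame, gene_col: str, chrom_col: str, rank_col: str) -> pd.DataFrame:
        d = d.reset_index(drop=True)
        gene = pd.factorize(d[gene_col])[0]
        chrom = pd.factorize(d[chrom_col])[0]
        rank = d[rank_col].to_numpy()
        score = d["score"].to_numpy()
        ga = d["gene_a"].to_numpy()
        gb = d["gene_b"].to_numpy()
        order = np.lexsort((rank, chrom, gene))
        keep: list[int] = []
        best = -1  # index (into d) of the best row of the open cluster
        prev = None
        for i in order:
            key = (gene[i], chrom[i])
            if prev is None or key != prev[0] or rank[i] - prev[1] > max_gap:
                if best >= 0:
                    keep.append(best)
                best = i
            elif (-score[i], ga[i], gb[i]) < (-score[best], ga[best], gb[best]):
                best = i
            prev = (key, rank[i])
        if best >= 0:
            keep.append(best)
        return d.loc[sorted(keep)]

    df = collapse_side(df, "gene_a", "chrom_b", "rank_b")
    df = collapse_side(df, "gene_b", "chrom_a", "rank_a")
    return df


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _best_chain(anchors: np.ndarray, max_gap: int) -> list[int] | None:
    """Best strictly-increasing chain over (ra, rb) anchor rows.

    ``anchors`` is an (n, 2) int array.  Returns row indices of the
    longest chain with gaps <= max_gap on both axes; among equally long
    chains the lexicographically smallest anchor sequence is returned.
    """
    n = len(anchors)
    if n == 0:
        return None
    order = np.lexsort((anchors[:, 1], anchors[:, 0]))
    ra = anchors[order, 0]
    rb = anchors[order, 1]
    f = np.ones(n, dtype=np.int64)
    preds: list[list[int]] = [[] for _ in range(n)]
    lo = 0
    for i in range(n):
        # candidate predecessors live in a bounded rank_a window
        while ra[lo] < ra[i] - max_gap - 1:
            lo += 1
        cand = [
            j
            for j in range(lo, i)
            if ra[j] < ra[i]
            and rb[j] < rb[i]
            and rb[i] - rb[j] - 1 <= max_gap
        ]
        if cand:
            fj = f[np.array(cand)]
            best = fj.max()
            f[i] = best + 1
            preds[i] = [j for j, v in zip(cand, fj) if v == best]

    chain_cache: dict[int, tuple] = {}

    def chain_of(i: int) -> tuple:
        # iterative DFS: chains can be thousands of anchors long
        stack = [i]
        while stack:
            k = stack[-1]
            if k in chain_cache:
                stack.pop()
                continue
            missing = [j for j in preds[k] if j not in chain_cache]
            if missing:
                stack.extend(missing)
                continue
            if not preds[k]:
                chain_cache[k] = ((int(ra[k]), int(rb[k])),)
            else:
                best_prev = min(chain_cache[j] for j in preds[k])
                chain_cache[k] = best_prev + ((int(ra[k]), int(rb[k])),)
            stack.pop()
        return chain_cache[i]

    fmax = int(f.max())
    ends = [i for i in range(n) if f[i] == fmax]
    best_chain = min(chain_of(i) for i in ends)
    pos = {(int(ra[i]), int(rb[i])): order[i] for i in range(n)}
    return [int(pos[p]) for p in best_chain]


def _chain_key(anchors: np.ndarray, rows: list[int], orientation: str) -> tuple:
    seq = tuple((int(anchors[r, 0]), int(anchors[r, 1])) for r in rows)
    return (-len(rows), seq, 0 if orientation == "+" else 1)


def detect_collinear_blocks(
    pairs: list[HomologPair],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    params: ChainParams | None = None,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into syntenic blocks between two genomes.

    Every anchor is used in at most one block; the returned blocks are
    sorted by ``(chrom_a, first rank_a)`` and numbered accordingly.
    """
    params = params or ChainParams()
    if not pairs:
        return []
    df = _resolve_anchors(pairs, ann_a, ann_b)
    df = _collapse_tandem(df, params.max_gap_genes)

    raw_blocks = []
    for (ca, cb), grp in df.groupby(["chrom_a", "chrom_b"], sort=True):
        anchors = grp[["rank_a", "rank_b"]].to_numpy(dtype=np.int64)
        meta = grp[["gene_a", "gene_b"]].to_numpy()
        alive = np.ones(len(anchors), dtype=bool)
        while alive.sum() >= params.min_anchors:
            idx_alive = np.flatnonzero(alive)
            sub = anchors[idx_alive]
            cands = []
            fwd = _best_chain(sub, params.max_gap_genes)
            if fwd is not None:
                cands.append(("+", fwd))
            flipped = sub.copy()
            flipped[:, 1] = -flipped[:, 1]
            rev = _best_chain(flipped, params.max_gap_genes)
            if rev is not None:
                cands.append(("-", rev))
            if not cands:
                break
            orientation, rows = min(
                cands, key=lambda c: _chain_key(sub, c[1], c[0])
            )
            if len(rows) < params.min_anchors:
                break
            chosen = idx_alive[rows]
            chosen = chosen[np.argsort(anchors[chosen, 0])]
            anchor_list = [
                (int(anchors[i, 0]), int(anchors[i, 1]), str(meta[i, 0]), str(meta[i, 1]))
                for i in chosen
            ]
            raw_blocks.append((ca, cb, orientation, anchor_list))
            alive[chosen] = False

    raw_blocks.sort(key=lambda b: (b[0], b[3][0][0], b[1], b[3][0][1]))
    blocks = []
    for i, (ca, cb, orientation, anchor_list) in enumerate(raw_blocks):
        blocks.append(
            SyntenyBlock(
                block_id=f"blk{i:04d}",
                genome_a=ann_a.genome_id,
                chrom_a=ca,
                genome_b=ann_b.genome_id,
                chrom_b=cb,
                anchors=anchor_list,
                orientation=orientation,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# chromosome correspondence
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceRow:
    counterpart_chrom: str
    anchored_fraction: float
    n_anchors: int
    patches: list[tuple[int, int]]  # inclusive rank_a intervals


@dataclass
class ChromCorrespondence:
    ref_chrom: str
    counterpart_genome: str
    rows: list[CorrespondenceRow] = field(default_factory=list)

    @property
    def total_anchors(self) -> int:
        return sum(r.n_anchors for r in self.rows)


def chromosome_correspondence(
    blocks: list[SyntenyBlock],
    ref_genome: str,
    other_genome: str,
    max_gap_genes: int = 25,
) -> list[ChromCorrespondence]:
    """Summarise which counterpart chromosomes each reference chromosome maps to.

    Fractions are anchors-to-that-counterpart over total anchored genes
    of the reference chromosome; patch intervals are maximal contiguous
    reference-rank runs (block spans on one counterpart chromosome
    merged when separated by <= ``max_gap_genes`` ranks).
    """
    rel = [
        b for b in blocks if b.genome_a == ref_genome and b.genome_b == other_genome
    ]
    by_ref: dict[str, list[SyntenyBlock]] = {}
    for b in rel:
        by_ref.setdefault(b.chrom_a, []).append(b)
    out = []
    for ref_chrom in sorted(by_ref):
        bs = by_ref[ref_chrom]
        total = sum(b.n_anchors for b in bs)
        rows = []
        by_cpt: dict[str, list[SyntenyBlock]] = {}
        for b in bs:
            by_cpt.setdefault(b.chrom_b, []).append(b)
        for cpt in sorted(by_cpt):
            cbs = by_cpt[cpt]
            n = sum(b.n_anchors for b in cbs)
            spans = sorted(b.span_a for b in cbs)
            patches: list[tuple[int, int]] = []
            for lo, hi in spans:
                if patches and lo - patches[-1][1] - 1 <= max_gap_genes:
                    patches[-1] = (patches[-1][0], max(patches[-1][1], hi))
                else:
                    patches.append((lo, hi))
            rows.append(CorrespondenceRow(cpt, n / total if total else 0.0, n, patches))
        out.append(ChromCorrespondence(ref_chrom, other_genome, rows))
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """One anchor per row, keyed by block_id."""
    rows = []
    for b in blocks:
        for ra, rb, ga, gb in b.anchors:
            rows.append(
                (b.block_id, b.genome_a, b.chrom_a, ra, ga, b.genome_b, b.chrom_b, rb, gb,
                 b.orientation)
            )
    return pd.DataFrame(
        rows,
        columns=["block_id", "genome_a", "chrom_a", "rank_a", "gene_a",
                 "genome_b", "chrom_b", "rank_b", "gene_b", "orientation"],
    )


def block_summary(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        (b.block_id, b.chrom_a, b.chrom_b, b.orientation, b.n_anchors,
         *b.span_a, *b.span_b, b.median_ks if b.median_ks is not None else float("nan"))
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors",
                 "start_a", "end_a", "start_b", "end_b", "median_ks"],
    )


def write_blocks(blocks: list[SyntenyBlock], path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def read_blocks(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for bid, grp in df.groupby("block_id", sort=True):
        grp = grp.sort_values("rank_a")
        first = grp.iloc[0]
        anchors = [
            (int(r.rank_a), int(r.rank_b), str(r.gene_a), str(r.gene_b))
            for r in grp.itertuples()
        ]
        blocks.append(
            SyntenyBlock(str(bid), str(first.genome_a), str(first.chrom_a),
                         str(first.genome_b), str(first.chrom_b), anchors,
                         str(first.orientation))
        )
    return blocks


# ---------------------------------------------------------------------------
# exhaustive reference chaining (small inputs)
# ---------------------------------------------------------------------------


def enumerate_best_chain(
    anchors: list[tuple[int, int]], max_gap: int
) -> tuple[str, list[tuple[int, int]]] | None:
    """Exhaustively search all monotone chains over <= ~30 anchors.

    Provided so that the dynamic-programming chainer can be validated
    against brute force; uses the same selection criterion (longest,
    then lexicographically smallest anchor sequence, ``+`` before
    ``-``).  Exponential — only for tiny inputs.
    """
    best: tuple | None = None
    best_res = None

    def ok(prev, nxt, sign):
        da = nxt[0] - prev[0]
        db = (nxt[1] - prev[1]) * sign
        return da > 0 and db > 0 and da - 1 <= max_gap and db - 1 <= max_gap

    for sign, orient in ((1, "+"), (-1, "-")):
        pts = sorted(anchors)

        def extend(chain):
            nonlocal best, best_res
            extended = False
            for p in pts:
                if p in chain:
                    continue
                if not chain or ok(chain[-1], p, sign):
                    if chain and p[0] <= chain[-1][0]:
                        continue
                    extend(chain + [p])
                    extended = True
            if chain and not extended:
                key = (-len(chain), tuple(chain), 0 if orient == "+" else 1)
                if best is None or key < best:
                    best = key
                    best_res = (orient, list(chain))

        extend([])
    return best_res
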