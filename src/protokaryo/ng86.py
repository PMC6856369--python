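"""Synonymous/nonsynonymous substitution counting (Nei–Gojobori 1986).

For each codon the number of synonymous *sites* is the fraction of the
three possible single-nucleotide changes at each position that preserve
the amino acid (changes to a stop codon count as nonsynonymous), so
``S + N = 3 * n_codons`` exactly.  Between two codons differing at k
positions, synonymous/nonsynonymous *differences* are averaged over all
k! mutational paths with equal weights; paths passing through a stop
codon are excluded (if every path is blocked, all paths are used).

Proportions are corrected for multiple hits with the Jukes–Cantor
formula, d = -(3/4) ln(1 - (4/3) p); p >= 3/4 is reported as saturated.

The 61x61 sense-codon difference tables are precomputed once per
genetic code, so counting over long alignments is a table lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


@lru_cache(maxsize=8)
def _code_maps(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = {}
    for c in CODONS:
        aa[c] = "*" if c in table.stop_codons else table.forward_table[c]
    return aa


@lru_cache(maxsize=8)
def _tables(table_id: int):
    """Per-codon synonymous sites and per-pair averaged (sd, nd)."""
    aa = _code_maps(table_id)
    n = len(CODONS)
    syn_sites = np.full(n, np.nan)
    for ci, codon in enumerate(CODONS):
        if aa[codon] == "*":
            continue
        s = 0.0
        for pos in range(3):
            for nt in NUCS:
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1:]
                if aa[mut] != "*" and aa[mut] == aa[codon]:
                    s += 1.0 / 3.0
        syn_sites[ci] = s

    sd = np.full((n, n), np.nan)
    nd = np.full((n, n), np.nan)
    for ci, ca in enumerate(CODONS):
        if aa[ca] == "*":
            continue
        for cj, cb in enumerate(CODONS):
            if aa[cb] == "*":
                continue
            diff = [p for p in range(3) if ca[p] != cb[p]]
            if not diff:
                sd[ci, cj] = nd[ci, cj] = 0.0
                continue
            paths = []
            for order in itertools.permutations(diff):
                cur = ca
                s = ns = 0.0
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if aa[nxt] == "*":
                        blocked = True
                        break
                    if aa[nxt] == aa[cur]:
                        s += 1.0
                    else:
                        ns += 1.0
                    cur = nxt
                if not blocked:
                    paths.append((s, ns))
            if not paths:  # every path runs through a stop: fall back to all paths
                for order in itertools.permutations(diff):
                    cur = ca
                    s = ns = 0.0
                    for pos in order:
                        nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                        if aa.get(nxt, "*") == aa[cur]:
                            s += 1.0
                        else:
                            ns += 1.0
                        cur = nxt
                    paths.append((s, ns))
            sd[ci, cj] = sum(p[0] for p in paths) / len(paths)
            nd[ci, cj] = sum(p[1] for p in paths) / len(paths)
    return syn_sites, sd, nd


@dataclass
class CodonAlignment:
    """A gap-free pairwise codon alignment."""

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"{self.gene_a}/{self.gene_b}: aligned lengths differ "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.gene_a}/{self.gene_b}: length not a multiple of 3")
        if len(self.seq_a) == 0:
            raise ValueError(f"{self.gene_a}/{self.gene_b}: empty alignment")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass
class NGCounts:
    """Site and difference counts plus Jukes–Cantor corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    ps: float
    pn: float
    Ks: float  # nan when saturated or S == 0
    Ka: float
    saturated_s: bool = False
    saturated_n: bool = False


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p), False


def ng86_counts(aln: CodonAlignment, table_id: int = 1) -> NGCounts:
    """Count synonymous/nonsynonymous sites and differences for one pair.

    Codons containing non-ACGT characters (gaps, ambiguity codes) are
    skipped.  An internal stop codon in either sequence is rejected with
    its codon position.
    """
    syn_sites, sd_tab, nd_tab = _tables(table_id)
    a = aln.seq_a.upper().replace("U", "T")
    b = aln.seq_b.upper().replace("U", "T")
    ia = _codon_indices(a)
    ib = _codon_indices(b)
    valid = (ia >= 0) & (ib >= 0)
    # trailing stop codons are tolerated and skipped together
    last = aln.n_codons - 1
    for name, idx in ((aln.gene_a, ia), (aln.gene_b, ib)):
        stops = np.flatnonzero((idx >= 0) & np.isnan(syn_sites[np.maximum(idx, 0)]))
        stops = stops[stops != last]
        if len(stops):
            raise ValueError(f"internal stop codon in {name} at codon {int(stops[0]) + 1}")
        valid &= ~((idx >= 0) & np.isnan(syn_sites[np.maximum(idx, 0)]))
    ia_v, ib_v = ia[valid], ib[valid]
    if len(ia_v) == 0:
        raise ValueError(f"{aln.gene_a}/{aln.gene_b}: no scorable codon columns")
    S = float((syn_sites[ia_v].sum() + syn_sites[ib_v].sum()) / 2.0)
    n_cod = int(len(ia_v))
    N = 3.0 * n_cod - S
    Sd = float(sd_tab[ia_v, ib_v].sum())
    Nd = float(nd_tab[ia_v, ib_v].sum())
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    if S > 0:
        Ks, sat_s = _jc_correct(ps)
    else:
        Ks, sat_s = float("nan"), False
    if N > 0:
        Ka, sat_n = _jc_correct(pn)
    else:
        Ka, sat_n = float("nan"), False
    return NGCounts(S, N, Sd, Nd, n_cod, ps, pn, Ks, Ka, sat_s, sat_n)


def _codon_indices(seq: str) -> np.ndarray:
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(len(out)):
        out[i] = CODON_INDEX.get(seq[3 * i: 3 * i + 3], -1)
    return out


def pairwise_ks(seq_a: str, seq_b: str, name_a: str = "a", name_b: str = "b",
                table_id: int = 1) -> float:
    """Convenience: Ks for one pre-aligned, equal-length CDS pair."""
    return ng86_counts(CodonAlignment(name_a, name_b, seq_a, seq_b), table_id).Ks
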