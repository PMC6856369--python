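"""Proto-chromosome inference and fusion/fission scenario reconstruction.

Given syntenic blocks between a reference genome and several counterpart
genomes, the ancestral chromosome complement is reconstructed from three
kinds of evidence:

* rule A — a reference chromosome whose gene content maps essentially
  one-to-one onto a single counterpart chromosome in every genome (two
  in a genome with a lineage-specific WGD) is itself a proto-chromosome;
* rule B — a reference chromosome that occurs in a *partite* manner,
  i.e. the same split into independent patches recurs across genomes,
  contributes one proto-chromosome per patch (the reference lineage
  fused them);
* rule C — patches from *different* reference chromosomes whose
  counterpart images are adjacent on a single chromosome in enough
  genomes are merged into one proto-chromosome (the reference lineage
  split it).

Both rules are applied by voting over atomic reference segments: a
split (or a cross-chromosome link) is accepted as ancestral only when
supported by at least ``min_support`` counterpart genomes *and* by more
genomes than contradict it — the parsimony tie-break that distinguishes
one event on the reference lineage from coincident independent events
on two counterpart lineages.  A WGD genome's two subgenome copies are
counted as separate witnesses.

The per-lineage scenario then counts fusions as (proto segments - 1)
summed over chromosomes and fissions as (chromosomes containing a
proto - expected copies) summed over protos, with expected copies 2 in
a WGD lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .synteny import SyntenyBlock


@dataclass
class KaryotypeParams:
    tau1: float = 0.8          # coverage a counterpart chromosome set must reach
    tau2: float = 0.8          # reciprocal-anchor fraction for "one-to-one"
    patch_min: int = 20        # anchors a patch needs to count as evidence
    min_support: int = 2       # genomes (WGD copies count separately) backing a split/link
    max_gap_genes: int = 25    # rank gap closing patches / defining adjacency
    breakpoint_tol: int = 5    # rank tolerance when clustering patch boundaries
    min_image_anchors: int = 5  # anchors for a counterpart image to be trusted
    min_run: int = 10          # genes for a proto segment to count in the scenario
    wgd_ratio_min: float = 1.6  # genome-wide proto copy ratio flagging a WGD lineage


@dataclass
class ProtoChromosome:
    proto_id: int
    member_segments: list[tuple[str, str, tuple[int, int]]]  # (genome, chrom, rank interval)
    support: list[str] = field(default_factory=list)

    def ref_segments(self, ref_genome: str):
        return [(c, iv) for g, c, iv in self.member_segments if g == ref_genome]


@dataclass
class KaryotypeScenario:
    events: dict[str, dict[str, int | bool]]  # genome -> {fusion, fission, wgd}
    composition: dict[str, dict[str, list[tuple[int, int, int]]]]
    # genome -> chrom -> [(proto_id, start_rank, end_rank_inclusive)]
    unplaced: dict[str, int] = field(default_factory=dict)


@dataclass
class KaryotypeResult:
    protos: list[ProtoChromosome]
    assignment: dict[str, dict[str, int]]  # genome -> gene_id -> proto_id
    classifications: dict[str, str]        # ref chrom -> preserved/partite/mosaic/unresolved
    segments: dict[str, list[tuple[int, int]]]  # ref chrom -> atomic segment rank intervals

    @property
    def n_protos(self) -> int:
        return len(self.protos)


# ---------------------------------------------------------------------------
# anchor table and atomic segmentation
# ---------------------------------------------------------------------------


def _anchor_table(blocks_by_genome: dict[str, list[SyntenyBlock]], ref: str) -> pd.DataFrame:
    rows = []
    for genome in sorted(blocks_by_genome):
        for b in blocks_by_genome[genome]:
            if b.genome_a != ref:
                raise ValueError(
                    f"blocks for {genome!r} must have the reference {ref!r} as genome_a"
                )
            for ra, rb, ga, gb in b.anchors:
                rows.append((genome, b.chrom_a, ra, ga, b.chrom_b, rb, gb))
    return pd.DataFrame(
        rows, columns=["genome", "ref_chrom", "ref_rank", "ref_gene",
                       "cpt_chrom", "cpt_rank", "cpt_gene"],
    )


def _patch_intervals(ranks: np.ndarray, max_gap: int) -> list[tuple[int, int, int]]:
    """Maximal runs of sorted ranks with gaps <= max_gap.

    Returns inclusive intervals with their anchor counts:
    (lo, hi, n_anchors).
    """
    if len(ranks) == 0:
        return []
    ranks = np.sort(ranks)
    cuts = np.flatnonzero(np.diff(ranks) > max_gap + 1)
    starts = np.concatenate([[0], cuts + 1])
    ends = np.concatenate([cuts, [len(ranks) - 1]])
    return [
        (int(ranks[s]), int(ranks[e]), int(e - s + 1)) for s, e in zip(starts, ends)
    ]


def _atomic_segments(
    tab: pd.DataFrame, ref_chrom: str, n_genes: int, p: KaryotypeParams
) -> list[tuple[int, int]]:
    """Partition a reference chromosome at recurrent patch boundaries.

    Boundaries are collected from every (genome, counterpart chromosome)
    patch of at least ``patch_min`` anchors, clustered within
    ``breakpoint_tol`` ranks, and used to cut [0, n_genes) into atomic
    segments (half-open rank intervals).
    """
    sub = tab[tab.ref_chrom == ref_chrom]
    cut_points: list[int] = []
    for (_g, _c), grp in sub.groupby(["genome", "cpt_chrom"], sort=True):
        for lo, hi, n in _patch_intervals(grp.ref_rank.to_numpy(), p.max_gap_genes):
            if n < p.patch_min:
                continue  # too small to count as patch evidence
            cut_points.extend([lo, hi + 1])
    cut_points = sorted(c for c in cut_points if p.breakpoint_tol < c < n_genes - p.breakpoint_tol)
    # merge clusters: use the median of each run of nearby cut points
    clustered: list[int] = []
    i = 0
    while i < len(cut_points):
        j = i
        while j + 1 < len(cut_points) and cut_points[j + 1] - cut_points[i] <= p.breakpoint_tol:
            j += 1
        clustered.append(int(np.median(cut_points[i:j + 1])))
        i = j + 1
    edges = [0] + clustered + [n_genes]
    segs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            segs.append((lo, hi))
    return segs


def _segment_images(
    tab: pd.DataFrame,
    segs_by_chrom: dict[str, list[tuple[int, int]]],
    genomes: list[str],
    p: KaryotypeParams,
) -> dict[tuple[str, int], dict[str, dict[str, tuple[int, int, int]]]]:
    """Counterpart placements of each atomic segment.

    Returns {(ref_chrom, seg_idx): {genome: {cpt_chrom: (lo, hi, n_anchors)}}}
    where (lo, hi) is the counterpart-rank span of the segment's anchors.
    """
    images: dict = {}
    for ref_chrom, segs in segs_by_chrom.items():
        sub = tab[tab.ref_chrom == ref_chrom]
        for si, (lo, hi) in enumerate(segs):
            seg_tab = sub[(sub.ref_rank >= lo) & (sub.ref_rank < hi)]
            per_genome: dict[str, dict[str, tuple[int, int, int]]] = {}
            for genome in genomes:
                gt = seg_tab[seg_tab.genome == genome]
                imgs: dict[str, tuple[int, int, int]] = {}
                for chrom, grp in gt.groupby("cpt_chrom", sort=True):
                    if len(grp) < p.min_image_anchors:
                        continue
                    imgs[str(chrom)] = (int(grp.cpt_rank.min()), int(grp.cpt_rank.max()),
                                        int(len(grp)))
                per_genome[genome] = imgs
            images[(ref_chrom, si)] = per_genome
    return images


def _spans_adjacent(a: tuple[int, int, int], b: tuple[int, int, int], max_gap: int) -> bool:
    gap = max(a[0] - b[1], b[0] - a[1]) - 1
    return gap <= max_gap


def _vote(
    imgs_s: dict[str, tuple[int, int, int]],
    imgs_t: dict[str, tuple[int, int, int]],
    wgd: bool,
    max_gap: int,
    require_adjacent: bool,
) -> tuple[int, int]:
    """(together, apart) witness counts contributed by one genome.

    For split voting (``require_adjacent=False``) sharing a counterpart
    chromosome is enough to count as "together": intra-chromosomal
    rearrangements on either lineage do not separate protos.  For link
    voting (rule C, ``require_adjacent=True``) the two images must be
    adjacent on the shared chromosome, because only physical adjacency
    witnesses an ancestral junction.
    """
    if not imgs_s or not imgs_t:
        return 0, 0
    shared = imgs_s.keys() & imgs_t.keys()
    if require_adjacent:
        shared = {c for c in shared if _spans_adjacent(imgs_s[c], imgs_t[c], max_gap)}
    cap = 2 if wgd else 1
    together = min(len(shared), cap)
    placements = min(len(imgs_s), len(imgs_t), cap)
    apart = max(0, placements - together)
    return together, apart


# ---------------------------------------------------------------------------
# preservation classification
# ---------------------------------------------------------------------------


def classify_preservation(
    blocks_by_genome: dict[str, list[SyntenyBlock]],
    ref_ann: GenomeAnnotation,
    wgd_genomes: set[str] = frozenset(),
    params: KaryotypeParams | None = None,
) -> dict[str, str]:
    """Classify each reference chromosome as preserved / partite / mosaic.

    A chromosome is *preserved* when, in every counterpart genome, at
    least ``tau1`` of its anchors fall on counterpart chromosomes (one,
    or two for a WGD genome) that reciprocally draw at least ``tau2``
    of their own anchors from this chromosome.  It is *partite* when it
    splits into >= 2 patch groups each passing the same reciprocal test
    on its own; anything else is *mosaic*.  Chromosomes with fewer than
    ``patch_min`` anchors are "unresolved".
    """
    p = params or KaryotypeParams()
    tab = _anchor_table(blocks_by_genome, ref_ann.genome_id)
    genomes = sorted(blocks_by_genome)
    cpt_totals = {
        (g, c): n for (g, c), n in tab.groupby(["genome", "cpt_chrom"]).size().items()
    }
    cpt_to_ref = {
        key: n for key, n in tab.groupby(["genome", "cpt_chrom", "ref_chrom"]).size().items()
    }

    def reciprocal_ok(genome: str, cpt_chrom: str, ref_chrom: str) -> bool:
        total = cpt_totals.get((genome, cpt_chrom), 0)
        if total == 0:
            return False
        return cpt_to_ref.get((genome, cpt_chrom, ref_chrom), 0) / total >= p.tau2

    def one_to_one(seg_tab: pd.DataFrame, ref_chrom: str) -> bool:
        for genome in genomes:
            gt = seg_tab[seg_tab.genome == genome]
            if len(gt) == 0:
                return False
            counts = gt.groupby("cpt_chrom").size().sort_values(ascending=False)
            allowed = 2 if genome in wgd_genomes else 1
            top = counts.iloc[:allowed]
            if top.sum() / len(gt) < p.tau1:
                return False
            if not all(reciprocal_ok(genome, c, ref_chrom) for c in top.index):
                return False
        return True

    out: dict[str, str] = {}
    for ref_chrom in ref_ann.chroms:
        sub = tab[tab.ref_chrom == ref_chrom]
        if len(sub) < p.patch_min:
            out[ref_chrom] = "unresolved"
            continue
        if one_to_one(sub, ref_chrom):
            out[ref_chrom] = "preserved"
            continue
        groups = _ancestral_groups(tab, ref_chrom, ref_ann.n_genes(ref_chrom),
                                   genomes, wgd_genomes, p)
        if len(groups) >= 2:
            ok = True
            for seg_ivs in groups:
                m = pd.Series(False, index=sub.index)
                for lo, hi in seg_ivs:
                    m |= (sub.ref_rank >= lo) & (sub.ref_rank < hi)
                part = sub[m]
                if len(part) < p.patch_min or not _part_one_to_one(
                    part, genomes, wgd_genomes, p, cpt_totals, cpt_to_ref, ref_chrom
                ):
                    ok = False
                    break
            out[ref_chrom] = "partite" if ok else "mosaic"
        else:
            out[ref_chrom] = "mosaic"
    return out


def _part_one_to_one(part, genomes, wgd_genomes, p, cpt_totals, cpt_to_ref, ref_chrom) -> bool:
    for genome in genomes:
        gt = part[part.genome == genome]
        if len(gt) == 0:
            return False
        counts = gt.groupby("cpt_chrom").size().sort_values(ascending=False)
        allowed = 2 if genome in wgd_genomes else 1
        top = counts.iloc[:allowed]
        if top.sum() / len(gt) < p.tau1:
            return False
        for c in top.index:
            total = cpt_totals.get((genome, c), 0)
            if total == 0 or cpt_to_ref.get((genome, c, ref_chrom), 0) / total < p.tau2:
                return False
    return True


def _ancestral_groups(tab, ref_chrom, n_genes, genomes, wgd_genomes, p):
    """Atomic segments of one chromosome grouped by accepted ancestral splits."""
    segs = _atomic_segments(tab, ref_chrom, n_genes, p)
    images = _segment_images(tab, {ref_chrom: segs}, genomes, p)
    eff = [si for si in range(len(segs))
           if any(images[(ref_chrom, si)][g] for g in genomes)]
    if not eff:
        return [segs] if segs else []
    groups: list[list[tuple[int, int]]] = [[segs[eff[0]]]]
    for prev, cur in zip(eff[:-1], eff[1:]):
        together = apart = 0
        for genome in genomes:
            t, a = _vote(
                images[(ref_chrom, prev)][genome],
                images[(ref_chrom, cur)][genome],
                genome in wgd_genomes,
                p.max_gap_genes,
                require_adjacent=False,
            )
            together += t
            apart += a
        if apart >= p.min_support and apart > together:
            groups.append([segs[cur]])
        else:
            groups[-1].append(segs[cur])
    return groups


# ---------------------------------------------------------------------------
# proto-chromosome inference
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def infer_proto_chromosomes(
    blocks_by_genome: dict[str, list[SyntenyBlock]],
    annotations: dict[str, GenomeAnnotation],
    ref_genome: str,
    wgd_genomes: set[str] = frozenset(),
    params: KaryotypeParams | None = None,
) -> KaryotypeResult:
    """Infer the ancestral chromosome set and assign every gene to a proto.

    ``blocks_by_genome`` maps each counterpart genome to its syntenic
    blocks against the reference (reference as genome_a).  Counterpart
    genes are assigned through their anchors, with unanchored genes
    interpolated between same-proto anchored neighbours.
    """
    p = params or KaryotypeParams()
    ref_ann = annotations[ref_genome]
    genomes = sorted(blocks_by_genome)
    tab = _anchor_table(blocks_by_genome, ref_genome)

    segs_by_chrom = {
        chrom: _atomic_segments(tab, chrom, ref_ann.n_genes(chrom), p)
        for chrom in ref_ann.chroms
    }
    images = _segment_images(tab, segs_by_chrom, genomes, p)
    seg_keys = [
        (chrom, si) for chrom in ref_ann.chroms for si in range(len(segs_by_chrom[chrom]))
    ]
    uf = _UnionFind(seg_keys)
    support: dict[tuple, list[str]] = {k: [] for k in seg_keys}

    # rule A / rule B: same-chromosome adjacent segments stay together
    # unless enough genomes independently place them on different
    # counterpart chromosomes.  Image-less slivers (e.g. a few genes at
    # an ancient junction) abstain: voting runs between their effective
    # neighbours and the sliver is attached to the nearest one.
    for chrom in ref_ann.chroms:
        segs = segs_by_chrom[chrom]
        eff = [si for si in range(len(segs))
               if any(images[(chrom, si)][g] for g in genomes)]
        for si in range(len(segs)):
            if si in eff or not eff:
                continue
            nearest = min(eff, key=lambda e: (abs(e - si), e))
            uf.union((chrom, si), (chrom, nearest))
        for prev, cur in zip(eff[:-1], eff[1:]):
            together = apart = 0
            for genome in genomes:
                t, a = _vote(images[(chrom, prev)][genome], images[(chrom, cur)][genome],
                             genome in wgd_genomes, p.max_gap_genes,
                             require_adjacent=False)
                together += t
                apart += a
            if not (apart >= p.min_support and apart > together):
                uf.union((chrom, prev), (chrom, cur))
            else:
                support[(chrom, cur)].append(f"partite:{apart}v{together}")

    # rule C: linked co-existence — across reference chromosomes, and
    # between non-adjacent segments of one chromosome (interleaved
    # compositions produced by stacked reference-lineage events)
    for i, ka in enumerate(seg_keys):
        for kb in seg_keys[i + 1:]:
            if ka[0] == kb[0] and abs(ka[1] - kb[1]) == 1:
                continue  # rank-adjacent pairs are governed by split voting
            link = unlink = 0
            for genome in genomes:
                t, a = _vote(images[ka][genome], images[kb][genome],
                             genome in wgd_genomes, p.max_gap_genes,
                             require_adjacent=True)
                link += t
                unlink += a
            if link >= p.min_support and link > unlink:
                uf.union(ka, kb)
                support[ka].append(f"linked_coexistence:{kb[0]}:{link}v{unlink}")

    # number protos by reference coordinates of their first segment
    comp: dict[tuple, list[tuple]] = {}
    for k in seg_keys:
        comp.setdefault(uf.find(k), []).append(k)
    ordered = sorted(comp.values(), key=lambda ks: min(ks))
    protos: list[ProtoChromosome] = []
    seg_to_proto: dict[tuple, int] = {}
    for pid, members in enumerate(ordered, start=1):
        segs = []
        sup: list[str] = []
        for k in sorted(members):
            chrom, si = k
            lo, hi = segs_by_chrom[chrom][si]
            segs.append((ref_genome, chrom, (lo, hi - 1)))
            sup.extend(support[k])
            seg_to_proto[k] = pid
        if not sup:
            sup = ["one_to_one"]
        protos.append(ProtoChromosome(pid, segs, sorted(set(sup))))

    # gene assignment: reference genes by segment, counterpart genes by anchor
    assignment: dict[str, dict[str, int]] = {g: {} for g in genomes}
    assignment[ref_genome] = {}
    for chrom in ref_ann.chroms:
        genes = ref_ann.genes_on(chrom)
        for si, (lo, hi) in enumerate(segs_by_chrom[chrom]):
            pid = seg_to_proto[(chrom, si)]
            for gl in genes[lo:hi]:
                assignment[ref_genome][gl.gene_id] = pid

    seg_lookup: dict[str, np.ndarray] = {}
    for chrom, segs in segs_by_chrom.items():
        seg_lookup[chrom] = np.array([lo for lo, _ in segs])
    if len(tab):
        ref_pid = []
        for r in tab.itertuples():
            si = int(np.searchsorted(seg_lookup[r.ref_chrom], r.ref_rank, side="right") - 1)
            ref_pid.append(seg_to_proto[(r.ref_chrom, si)])
        tab = tab.assign(proto=ref_pid)
        for genome in genomes:
            gt = tab[tab.genome == genome]
            votes = gt.groupby("cpt_gene")["proto"].agg(
                lambda s: s.value_counts().idxmax()
            )
            assignment[genome] = votes.to_dict()

    for genome in genomes:
        _interpolate_assignment(assignment[genome], annotations[genome])

    # record counterpart member segments on each proto
    for genome in genomes:
        ann = annotations[genome]
        for chrom in ann.chroms:
            runs = _proto_runs(ann, assignment[genome], chrom, p)
            for pid, lo, hi in runs:
                protos[pid - 1].member_segments.append((genome, chrom, (lo, hi)))

    classifications = classify_preservation(blocks_by_genome, ref_ann, wgd_genomes, p)
    segments = {
        chrom: [(lo, hi - 1) for lo, hi in segs] for chrom, segs in segs_by_chrom.items()
    }
    return KaryotypeResult(protos, assignment, classifications, segments)


def _interpolate_assignment(assign: dict[str, int], ann: GenomeAnnotation) -> None:
    """Fill unanchored genes flanked by same-proto anchored neighbours."""
    for chrom in ann.chroms:
        genes = ann.genes_on(chrom)
        labels = [assign.get(g.gene_id) for g in genes]
        i = 0
        n = len(labels)
        while i < n:
            if labels[i] is None:
                j = i
                while j < n and labels[j] is None:
                    j += 1
                left = labels[i - 1] if i > 0 else None
                right = labels[j] if j < n else None
                fill = left if (left is not None and left == right) else None
                if fill is None and left is None and right is not None:
                    fill = right  # leading run: extend inward from the first anchor
                if fill is None and right is None and left is not None:
                    fill = left
                if fill is not None:
                    for k in range(i, j):
                        labels[k] = fill
                i = j
            else:
                i += 1
        for g, lab in zip(genes, labels):
            if lab is not None:
                assign[g.gene_id] = lab


def _proto_runs(
    ann: GenomeAnnotation, assign: dict[str, int], chrom: str, p: KaryotypeParams
) -> list[tuple[int, int, int]]:
    """Maximal proto runs (proto_id, start_rank, end_rank) along one chromosome.

    Gaps of unassigned genes shorter than ``max_gap_genes`` are
    absorbed; runs shorter than ``min_run`` genes are treated as noise
    and dropped.
    """
    genes = ann.genes_on(chrom)
    labeled = [(g.rank, assign[g.gene_id]) for g in genes if g.gene_id in assign]
    runs: list[list[int]] = []
    for rank, pid in labeled:
        if runs and runs[-1][0] == pid and rank - runs[-1][2] - 1 <= p.max_gap_genes:
            runs[-1][2] = rank
            runs[-1][3] += 1
        else:
            runs.append([pid, rank, rank, 1])
    merged: list[list[int]] = []
    for r in runs:
        if r[3] < p.min_run:
            continue
        if merged and merged[-1][0] == r[0] and r[1] - merged[-1][2] - 1 <= p.max_gap_genes:
            merged[-1][2] = r[2]
            merged[-1][3] += r[3]
        else:
            merged.append(r)
    return [(r[0], r[1], r[2]) for r in merged]


# ---------------------------------------------------------------------------
# evolutionary scenario
# ---------------------------------------------------------------------------


def reconstruct_scenario(
    result: KaryotypeResult,
    annotations: dict[str, GenomeAnnotation],
    params: KaryotypeParams | None = None,
) -> KaryotypeScenario:
    """Count fusions and fissions per lineage from the proto decomposition.

    For each genome every chromosome is decomposed into maximal
    proto-segments; fusions = sum over chromosomes of (segments - 1)
    and fissions = sum over protos of (chromosomes containing it minus
    the expected copy number), which is 2 when the genome-wide proto
    copy ratio flags a lineage-specific WGD.
    """
    p = params or KaryotypeParams()
    events: dict[str, dict] = {}
    composition: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
    unplaced: dict[str, int] = {}
    for genome in sorted(annotations):
        ann = annotations[genome]
        assign = result.assignment.get(genome, {})
        comp: dict[str, list[tuple[int, int, int]]] = {}
        for chrom in ann.chroms:
            runs = _proto_runs(ann, assign, chrom, p)
            if runs:
                comp[chrom] = runs
        composition[genome] = comp
        chroms_per_proto: dict[int, set[str]] = {}
        n_segments = 0
        for chrom, runs in comp.items():
            n_segments += len(runs)
            for pid, _, _ in runs:
                chroms_per_proto.setdefault(pid, set()).add(chrom)
        fusion = sum(max(0, len(runs) - 1) for runs in comp.values())
        n_present = len(chroms_per_proto)
        copy_ratio = (
            sum(len(cs) for cs in chroms_per_proto.values()) / n_present if n_present else 0.0
        )
        wgd = copy_ratio >= p.wgd_ratio_min
        expected = 2 if wgd else 1
        fission = sum(max(0, len(cs) - expected) for cs in chroms_per_proto.values())
        events[genome] = {"fusion": fusion, "fission": fission, "wgd": wgd}
        n_assigned = sum(1 for g in ann.loci if g.gene_id in assign)
        unplaced[genome] = len(ann) - n_assigned
    return KaryotypeScenario(events, composition, unplaced)


def assignment_frame(result: KaryotypeResult, annotations: dict[str, GenomeAnnotation]):
    """Long-format table of the gene -> proto assignment (for TSV export)."""
    rows = []
    for genome in sorted(result.assignment):
        ann = annotations[genome]
        for chrom in ann.chroms:
            for g in ann.genes_on(chrom):
                pid = result.assignment[genome].get(g.gene_id)
                rows.append((genome, chrom, g.rank, g.gene_id,
                             pid if pid is not None else -1))
    return pd.DataFrame(rows, columns=["genome", "chrom", "rank", "gene_id", "proto_id"])
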