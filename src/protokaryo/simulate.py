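"""Ground-truthed synthetic data for every pipeline stage.

Four generators emit inputs in exactly the formats the analysis modules
consume, together with the truth needed to score them:

* :func:`simulate_karyotype_evolution` — gene orders descending from an
  ancestor of ``n_proto`` chromosomes through fusions, fissions,
  inversions, optional WGD with fractionation, and gene loss; homolog
  pairs derive from the true orthology (plus a configurable fraction of
  spurious pairs mimicking off-diagonal BLAST hits).
* :func:`simulate_coding_divergence` — codon sequence pairs whose
  synonymous divergence is placed entirely at fourfold-degenerate third
  positions evolving under Jukes–Cantor at the requested Ks, so the
  counting estimator can be validated against a known target.
* :func:`simulate_ltr_cohort` — LTR end pairs evolved independently
  under Kimura's two-parameter model (ts/tv rate ratio kappa) at rate
  mu for specified ages; expected end-to-end divergence is 2*mu*age.
* :func:`simulate_population` — multi-group biallelic genotype panels
  with group-specific diversity targets (wild >> landrace >>
  cultivated), planted low-diversity sweep regions, per-site depths and
  controllable heterozygosity/violation patterns for filter testing.

All generators are bit-reproducible given (config, seed).  Allele
frequencies use a stylised Beta spectrum moment-matched to the pi
target rather than a coalescent — adequate for ranking and recovery
checks, not for demographic inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneLocus, GenomeAnnotation, HomologPair
from .ltr import LTRElement
from .variants import HET, HOM_ALT, HOM_REF, MISSING, VariantPanel

# ---------------------------------------------------------------------------
# karyotype evolution
# ---------------------------------------------------------------------------


@dataclass
class LineageSpec:
    """Events applied on the branch leading to one extant genome."""

    n_fusion: int = 0
    n_fission: int = 0
    n_inversion: int = 0
    n_translocation: int = 0
    wgd: bool = False
    retention_after_wgd: float = 0.55
    gene_loss: float = 0.03  # per-gene loss probability on the branch
    rate: float = 1.0        # molecular rate multiplier (for true Ks bookkeeping)


@dataclass
class KaryotypeSimConfig:
    n_proto: int = 15
    genes_per_proto: int = 200
    lineages: dict[str, LineageSpec] = field(default_factory=dict)
    min_segment_genes: int = 30   # fission breakpoints keep both parts at least this big
    noise_pair_rate: float = 0.02  # spurious homolog pairs per true pair
    gene_len: int = 1000
    gene_spacing: int = 3000
    ortholog_ks_base: float = 0.25  # per unit summed rate, for true-Ks bookkeeping


@dataclass
class SimTruth:
    seed: int
    event_log: list[tuple] = field(default_factory=list)
    true_proto: dict[str, dict[str, int]] = field(default_factory=dict)
    true_homology: dict[tuple[str, str], float] = field(default_factory=dict)
    true_sweeps: list[tuple[str, int, int, str]] = field(default_factory=list)
    true_insertion_times: dict[str, float] = field(default_factory=dict)
    group_pi_targets: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class KaryotypeSim:
    annotations: dict[str, GenomeAnnotation]
    pairs: dict[tuple[str, str], list[HomologPair]]
    truth: SimTruth


def _apply_events(chroms, spec: LineageSpec, rng, cfg, log, lineage):
    """Mutate a list of chromosomes (lists of (ancestral_gene, proto)) in place."""
    if spec.wgd:
        copies = []
        for ci, genes in enumerate(chroms):
            kept = [g for g in genes if rng.random() < spec.retention_after_wgd]
            copies.append(kept)
        log.append((lineage, "WGD", None))
        chroms.extend(c for c in copies if c)

    ops = (["fusion"] * spec.n_fusion + ["fission"] * spec.n_fission
           + ["inversion"] * spec.n_inversion
           + ["translocation"] * spec.n_translocation)
    rng.shuffle(ops)
    for op in ops:
        if op == "fusion" and len(chroms) >= 2:
            i, j = rng.choice(len(chroms), size=2, replace=False)
            a, b = chroms[i], chroms[j]
            if rng.random() < 0.5:
                b = b[::-1]
            log.append((lineage, "fusion", (len(a), len(b))))
            merged = a + b
            chroms[:] = [c for k, c in enumerate(chroms) if k not in (i, j)] + [merged]
        elif op == "fission":
            big = [k for k, c in enumerate(chroms) if len(c) >= 2 * cfg.min_segment_genes]
            if not big:
                raise ValueError(
                    f"lineage {lineage}: no chromosome long enough to fission "
                    f"(need >= {2 * cfg.min_segment_genes} genes)"
                )
            k = int(rng.choice(big))
            c = chroms[k]
            cut = int(rng.integers(cfg.min_segment_genes, len(c) - cfg.min_segment_genes + 1))
            log.append((lineage, "fission", (k, cut)))
            chroms[k:k + 1] = [c[:cut], c[cut:]]
        elif op == "inversion":
            k = int(rng.integers(len(chroms)))
            c = chroms[k]
            if len(c) < 4:
                continue
            lo = int(rng.integers(0, len(c) - 1))
            hi = int(rng.integers(lo + 1, len(c)))
            c[lo:hi + 1] = c[lo:hi + 1][::-1]
            log.append((lineage, "inversion", (k, lo, hi)))
        elif op == "translocation" and len(chroms) >= 2:
            i, j = rng.choice(len(chroms), size=2, replace=False)
            a, b = chroms[i], chroms[j]
            if len(a) < 2 or len(b) < 2:
                continue
            ca = int(rng.integers(1, len(a)))
            cb = int(rng.integers(1, len(b)))
            chroms[i], chroms[j] = a[:ca] + b[cb:], b[:cb] + a[ca:]
            log.append((lineage, "translocation", (i, j, ca, cb)))

    if spec.gene_loss > 0:
        for k, c in enumerate(chroms):
            keep = [g for g in c if rng.random() >= spec.gene_loss]
            chroms[k] = keep
        log.append((lineage, "gene_loss", spec.gene_loss))
    chroms[:] = [c for c in chroms if c]


def simulate_karyotype_evolution(cfg: KaryotypeSimConfig, seed: int) -> KaryotypeSim:
    """Evolve an ancestor of ``n_proto`` chromosomes into extant genomes.

    Each lineage descends independently from the ancestor (a star
    phylogeny), which is exactly the setting of the proto-chromosome
    rules: recurrence across independent descendants is what marks a
    feature as ancestral.
    """
    if len(cfg.lineages) < 2:
        raise ValueError("at least 2 lineages are required")
    rng = np.random.default_rng(seed)
    ancestor = []
    for p in range(cfg.n_proto):
        ancestor.append([(f"A{p + 1:02d}_{i:04d}", p + 1) for i in range(cfg.genes_per_proto)])

    truth = SimTruth(seed=seed)
    annotations: dict[str, GenomeAnnotation] = {}
    gene_origin: dict[str, dict[str, tuple[str, int]]] = {}

    for lineage in sorted(cfg.lineages):
        spec = cfg.lineages[lineage]
        chroms = [list(c) for c in ancestor]
        _apply_events(chroms, spec, rng, cfg, truth.event_log, lineage)
        loci = []
        origin: dict[str, tuple[str, int]] = {}
        proto_of: dict[str, int] = {}
        counter = itertools.count(1)
        for ci, genes in enumerate(chroms, start=1):
            chrom = f"{lineage}_chr{ci:02d}"
            for gi, (anc, proto) in enumerate(genes):
                gid = f"{lineage}G{next(counter):05d}"
                start = gi * cfg.gene_spacing
                loci.append(GeneLocus(gid, chrom, start, start + cfg.gene_len,
                                      "+" if rng.random() < 0.5 else "-"))
                origin[gid] = (anc, proto)
                proto_of[gid] = proto
        chrom_lengths = {
            f"{lineage}_chr{ci:02d}": len(genes) * cfg.gene_spacing + cfg.gene_len
            for ci, genes in enumerate(chroms, start=1)
        }
        annotations[lineage] = GenomeAnnotation.from_loci(lineage, loci, chrom_lengths)
        gene_origin[lineage] = origin
        truth.true_proto[lineage] = proto_of

    pairs: dict[tuple[str, str], list[HomologPair]] = {}
    lineages = sorted(cfg.lineages)
    for ga, gb in itertools.combinations(lineages, 2):
        plist = _homolog_pairs(gene_origin[ga], gene_origin[gb], cfg, rng,
                               cfg.lineages[ga], cfg.lineages[gb], truth)
        pairs[(ga, gb)] = plist
    for g in lineages:  # intra-genome paralogs (present after a WGD)
        plist = _paralog_pairs(gene_origin[g], cfg, rng)
        if plist:
            pairs[(g, g)] = plist
    return KaryotypeSim(annotations, pairs, truth)


def _homolog_pairs(origin_a, origin_b, cfg, rng, spec_a, spec_b, truth):
    by_anc_b: dict[str, list[str]] = {}
    for gid, (anc, _p) in origin_b.items():
        by_anc_b.setdefault(anc, []).append(gid)
    out = []
    ks_base = cfg.ortholog_ks_base * (spec_a.rate + spec_b.rate)
    for gid_a, (anc, _p) in sorted(origin_a.items()):
        for gid_b in sorted(by_anc_b.get(anc, [])):
            score = float(300 + rng.normal(0, 15))
            out.append(HomologPair(gid_a, gid_b, score, 1e-50))
            truth.true_homology[(gid_a, gid_b)] = float(
                max(0.01, ks_base + rng.normal(0, 0.05))
            )
    n_noise = int(round(cfg.noise_pair_rate * len(out)))
    ids_a, ids_b = sorted(origin_a), sorted(origin_b)
    for _ in range(n_noise):
        ga = ids_a[int(rng.integers(len(ids_a)))]
        gb = ids_b[int(rng.integers(len(ids_b)))]
        if origin_a[ga][0] == origin_b[gb][0]:
            continue
        out.append(HomologPair(ga, gb, float(60 + rng.normal(0, 10)), 1e-6))
    return out


def _paralog_pairs(origin, cfg, rng):
    by_anc: dict[str, list[str]] = {}
    for gid, (anc, _p) in origin.items():
        by_anc.setdefault(anc, []).append(gid)
    out = []
    for anc in sorted(by_anc):
        gids = sorted(by_anc[anc])
        for ga, gb in itertools.combinations(gids, 2):
            out.append(HomologPair(ga, gb, float(250 + rng.normal(0, 15)), 1e-40))
    return out


# ---------------------------------------------------------------------------
# coding-sequence divergence
# ---------------------------------------------------------------------------

# codon families whose third position is fourfold degenerate while any
# first/second-position change is nonsynonymous (no stop adjacency at
# the third position): Ala, Gly, Pro, Thr, Val
_FD_PREFIXES = ["GC", "GG", "CC", "AC", "GT"]
_NUCS = np.array(list("ACGT"))


def simulate_coding_divergence(
    n_pairs: int,
    ks_target: float,
    codons_per_gene: int,
    seed: int,
    ka_target: float = 0.0,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Generate CDS pairs whose expected synonymous divergence is ``ks_target``.

    Sequences are built from codon families with a fourfold-degenerate
    third position and fully nonsynonymous first two positions, so
    every codon contributes exactly one synonymous site.  Third
    positions then diverge under Jukes–Cantor: a site differs with
    probability (3/4)(1 - exp(-(4/3) Ks)), which the NG86 + JC pipeline
    inverts without bias.  Optional nonsynonymous divergence is placed
    at first positions the same way (stop-creating draws are resampled).

    Returns ([(pair_id, seq_a, seq_b), ...], truth_dict).
    """
    if not 0 <= ks_target < 3:
        raise ValueError(f"ks_target {ks_target} outside the datable range [0, 3)")
    rng = np.random.default_rng(seed)
    p_diff = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * ks_target))
    p_diff_n = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * ka_target)) if ka_target > 0 else 0.0
    pairs = []
    for i in range(n_pairs):
        prefixes = rng.choice(len(_FD_PREFIXES), size=codons_per_gene)
        thirds = rng.integers(0, 4, size=codons_per_gene)
        seq_a = "".join(
            _FD_PREFIXES[p] + _NUCS[t] for p, t in zip(prefixes, thirds)
        )
        thirds_b = thirds.copy()
        flip = rng.random(codons_per_gene) < p_diff
        shift = rng.integers(1, 4, size=codons_per_gene)
        thirds_b[flip] = (thirds_b[flip] + shift[flip]) % 4
        codons_b = [
            _FD_PREFIXES[p] + _NUCS[t] for p, t in zip(prefixes, thirds_b)
        ]
        if p_diff_n > 0:
            # both first and second positions are fully nonsynonymous in
            # these codon families; draws creating a stop are resampled
            for pos in (0, 1):
                flip_n = rng.random(codons_per_gene) < p_diff_n
                for j in np.flatnonzero(flip_n):
                    cod = codons_b[j]
                    while True:
                        nt = str(_NUCS[int(rng.integers(0, 4))])
                        cand = cod[:pos] + nt + cod[pos + 1:]
                        if nt != cod[pos] and cand not in ("TGA", "TAA", "TAG"):
                            codons_b[j] = cand
                            break
        seq_b = "".join(codons_b)
        pairs.append((f"pair{i:05d}", seq_a, seq_b))
    truth = {"ks_target": ks_target, "ka_target": ka_target, "p_diff": float(p_diff)}
    return pairs, truth


def simulate_lineage_ks_samples(
    rates: dict[str, float],
    grape: str,
    seed: int,
    t_ech: float = 1.2,
    t_cct: float = 0.75,
    n_per_event: int = 1500,
    rel_sd: float = 0.12,
) -> dict[str, np.ndarray]:
    """Paralog Ks samples for lineages with different molecular rates.

    Each species' ECH (and, for non-grape species, CCT) duplicate
    cohort is drawn around ``t_event * rate`` with proportional spread:
    the synthetic analogue of a whole-genome-event peak shifted by
    lineage rate.  ``t_ech``/``t_cct`` are the base peak positions (Ks
    units at rate 1).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sp in sorted(rates):
        r = rates[sp]
        parts = [rng.normal(t_ech * r, rel_sd * t_ech * r, n_per_event)]
        if sp != grape:
            parts.append(rng.normal(t_cct * r, rel_sd * t_cct * r, n_per_event))
        out[sp] = np.concatenate(parts)
    return out


# ---------------------------------------------------------------------------
# LTR cohorts
# ---------------------------------------------------------------------------


def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after divergence d (subs/site)."""
    e1 = np.exp(-4.0 * d / (kappa + 2.0))
    e2 = np.exp(-2.0 * (kappa + 1.0) * d / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv_each)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _evolve_k80(seq: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    p_ts, p_tv = _k80_probs(d, kappa)
    u = rng.random(len(seq))
    out = seq.copy()
    for i in np.flatnonzero(u < p_ts + 2 * p_tv):
        base = seq[i]
        if u[i] < p_ts:
            out[i] = _TRANSITION[base]
        elif u[i] < p_ts + p_tv:
            out[i] = _TRANSVERSIONS[base][0]
        else:
            out[i] = _TRANSVERSIONS[base][1]
    return out


def simulate_ltr_cohort(
    ages_mixture: dict[float, float],
    mu: float,
    n_elements: int,
    ltr_len: int,
    seed: int,
    kappa: float = 2.0,
) -> tuple[list[LTRElement], SimTruth]:
    """Generate LTR elements whose two ends diverged for known ages.

    ``ages_mixture`` maps age (years) -> mixture weight.  Both ends
    accumulate substitutions independently at mu per site per year with
    ts/tv rate ratio ``kappa``, so the expected K2p distance between
    the ends is 2*mu*age.  Elements whose expected divergence is beyond
    K2p saturation are flagged in the truth record.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    ages = np.array(sorted(ages_mixture))
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    w = np.array([ages_mixture[a] for a in ages], dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed)
    elements = []
    fams = ["Copia", "Gypsy"]
    for i in range(n_elements):
        age = float(ages[rng.choice(len(ages), p=w)])
        anc = _NUCS[rng.integers(0, 4, size=ltr_len)]
        d_branch = mu * age
        l5 = "".join(_evolve_k80(anc, d_branch, kappa, rng))
        l3 = "".join(_evolve_k80(anc, d_branch, kappa, rng))
        eid = f"ltr{i:05d}"
        start = int(rng.integers(0, 50_000_000))
        el = LTRElement(eid, "chr1", start, start + 2 * ltr_len + 4000,
                        fams[int(rng.integers(2))], l5, l3)
        elements.append(el)
        truth.true_insertion_times[eid] = age
        if 2 * mu * age >= 0.7:  # near K2p saturation for kappa ~ 2
            truth.extras.setdefault("near_saturation", []).append(eid)
    truth.extras["mu"] = mu
    truth.extras["kappa"] = kappa
    return elements, truth


def simulate_ltr_ortholog_pairs(
    n_pairs: int, mu: float, divergence_time_years: float, seq_len: int, seed: int,
    kappa: float = 2.0,
) -> list[tuple[str, str]]:
    """Orthologous insertion sequences for clock calibration.

    Each pair descends from one ancestral insertion and the two copies
    diverge for ``divergence_time_years`` at rate mu, mirroring
    orthologous LTR insertions shared by two species.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        anc = _NUCS[rng.integers(0, 4, size=seq_len)]
        a = "".join(_evolve_k80(anc, mu * divergence_time_years, kappa, rng))
        b = "".join(_evolve_k80(anc, mu * divergence_time_years, kappa, rng))
        out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# population panels
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    chrom: str
    start: int  # bp, half-open
    end: int
    stage: str  # "domestication" (reduces L and C) | "improvement" (reduces C)


@dataclass
class PopulationSimConfig:
    """Defaults model a resequencing panel of an inbred cucurbit crop:
    13 wild, 16 landrace and 117 cultivated accessions with genome-wide
    diversity 5.9, 1.1 and 0.4 (x 1e-3) respectively."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 12_000_000}
    )
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"W": 13, "L": 16, "C1": 58, "C2": 59}
    )
    pi_targets: dict[str, float] = field(
        default_factory=lambda: {"W": 5.9e-3, "L": 1.1e-3, "C": 0.4e-3}
    )
    snp_density: float = 0.03     # candidate polymorphic sites per bp
    beta_shape: float = 0.8       # Beta(a, a) allele-frequency spectrum
    selfing: float = 0.95         # fraction of genotypes drawn as homozygotes
    sweeps: list[SweepSpec] = field(default_factory=list)
    sweep_strength: float = 10.0  # fold reduction of polymorphism inside a sweep
    depth_mean: float = 2200.0    # total panel depth per site (negative binomial)
    depth_shape: float = 10.0
    # engineered filter violations (fractions of emitted sites)
    frac_multiallelic: float = 0.0
    frac_depth_low: float = 0.0
    frac_depth_high: float = 0.0
    frac_adjacent: float = 0.0
    frac_het_excess: float = 0.0


@dataclass
class PopulationSim:
    panel: VariantPanel
    groups: dict[str, str]  # sample -> group label (W/L/C1/C2)
    truth: SimTruth

    def samples_of(self, group: str) -> list[str]:
        """Samples of one group; "C" means the union of C1 and C2."""
        if group == "C":
            return [s for s, g in self.groups.items() if g in ("C1", "C2")]
        return [s for s, g in self.groups.items() if g == group]


def _expected_het(a: float) -> float:
    # E[2p(1-p)] for p ~ Beta(a, a)
    var = (a * a) / ((2 * a) ** 2 * (2 * a + 1))
    return 2.0 * (0.5 - (var + 0.25))


def simulate_population(cfg: PopulationSimConfig, seed: int) -> PopulationSim:
    """Generate a multi-group genotype panel with planted sweeps.

    Candidate sites are laid down at ``snp_density`` per bp; each group
    is independently polymorphic at a site with probability chosen so
    that the group's expected per-bp diversity matches its target, with
    allele frequencies from a symmetric Beta spectrum.  Inside a sweep
    the derived group's polymorphism probability is divided by
    ``sweep_strength``.  Genotypes are mostly homozygous (selfing-like);
    depths are negative binomial.
    """
    rng = np.random.default_rng(seed)
    groups = ["W", "L", "C"]
    eh = _expected_het(cfg.beta_shape)
    q = {}
    for g in groups:
        q[g] = cfg.pi_targets[g] / (cfg.snp_density * eh)
        if q[g] > 1:
            raise ValueError(
                f"pi target {cfg.pi_targets[g]} for group {g} unreachable at "
                f"snp_density {cfg.snp_density}; increase the density"
            )
    exp_window_s = min(q.values()) * cfg.snp_density * 200_000
    if exp_window_s < 1:
        import warnings

        warnings.warn("pi target implies <1 segregating site per 200 kb window")

    sample_names: list[str] = []
    group_of: dict[str, str] = {}
    for g in sorted(cfg.n_samples):
        for i in range(cfg.n_samples[g]):
            s = f"{g}_{i:03d}"
            sample_names.append(s)
            group_of[s] = g
    # analysis groups: C = C1 + C2
    members = {
        "W": [s for s in sample_names if group_of[s] == "W"],
        "L": [s for s in sample_names if group_of[s] == "L"],
        "C": [s for s in sample_names if group_of[s] in ("C1", "C2")],
    }
    col_of = {s: i for i, s in enumerate(sample_names)}

    truth = SimTruth(seed=seed, group_pi_targets=dict(cfg.pi_targets))
    truth.true_sweeps = [(s.chrom, s.start, s.end, s.stage) for s in cfg.sweeps]

    all_chrom, all_pos, all_ref, all_alt, all_gt, all_depth = [], [], [], [], [], []
    vtypes, ilens = [], []
    for chrom in sorted(cfg.chrom_lengths):
        L = cfg.chrom_lengths[chrom]
        n_cand = int(round(cfg.snp_density * L))
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(n_cand, L), replace=False))

        reduction = {g: np.ones(len(pos)) for g in groups}
        for sw in cfg.sweeps:
            if sw.chrom != chrom:
                continue
            inside = (pos > sw.start) & (pos <= sw.end)
            targets = ("L", "C") if sw.stage == "domestication" else ("C",)
            for g in targets:
                reduction[g][inside] /= cfg.sweep_strength

        gt = np.full((len(pos), len(sample_names)), HOM_REF, dtype=np.int8)
        any_poly = np.zeros(len(pos), dtype=bool)
        for g in groups:
            poly = rng.random(len(pos)) < q[g] * reduction[g]
            any_poly |= poly
            idx = np.flatnonzero(poly)
            p = rng.beta(cfg.beta_shape, cfg.beta_shape, size=len(idx))
            cols = np.array([col_of[s] for s in members[g]])
            # selfing-like genotypes: mostly homozygotes at frequency p
            u_self = rng.random((len(idx), len(cols)))
            hom_alt = rng.random((len(idx), len(cols))) < p[:, None]
            a1 = rng.random((len(idx), len(cols))) < p[:, None]
            a2 = rng.random((len(idx), len(cols))) < p[:, None]
            outcross = u_self >= cfg.selfing
            codes = np.where(hom_alt, HOM_ALT, HOM_REF).astype(np.int8)
            oc_codes = (a1.astype(np.int8) + a2.astype(np.int8))
            oc_codes = np.where(oc_codes == 1, HET, np.where(oc_codes == 2, HOM_ALT,
                                                             HOM_REF)).astype(np.int8)
            codes = np.where(outcross, oc_codes, codes)
            gt[np.ix_(idx, cols)] = codes

        keep = np.flatnonzero(any_poly)
        pos = pos[keep]
        gt = gt[keep]
        n = len(pos)
        refs = _NUCS[rng.integers(0, 4, size=n)]
        alt_shift = rng.integers(1, 4, size=n)
        alts = _NUCS[(np.searchsorted(_NUCS, refs) + alt_shift) % 4]
        p_nb = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
        depth = rng.negative_binomial(cfg.depth_shape, p_nb, size=n)

        alt_tuples = [(a,) for a in alts]
        chrom_arr = np.array([chrom] * n, dtype=object)
        vt = ["SNP"] * n
        il = [0] * n

        # engineered violations for filter testing
        viol: dict[str, list[int]] = {}
        free = np.arange(n)
        rng.shuffle(free)
        cursor = 0

        def take(frac):
            nonlocal cursor
            k = int(round(frac * n))
            sel = free[cursor:cursor + k]
            cursor += k
            return np.sort(sel)

        sel = take(cfg.frac_multiallelic)
        for i in sel:
            third = _NUCS[int(rng.integers(0, 4))]
            while third in (refs[i], alt_tuples[i][0]):
                third = _NUCS[int(rng.integers(0, 4))]
            alt_tuples[i] = (alt_tuples[i][0], third)
        viol["multiallelic"] = list(sel)
        sel = take(cfg.frac_depth_low)
        depth[sel] = rng.integers(0, 151, size=len(sel))
        viol["depth_low"] = list(sel)
        sel = take(cfg.frac_depth_high)
        depth[sel] = rng.integers(6570, 9000, size=len(sel))
        viol["depth_high"] = list(sel)
        sel = take(cfg.frac_het_excess)
        for i in sel:
            n_het = max(3, int(0.4 * len(sample_names)))
            het_cols = rng.choice(len(sample_names), size=n_het, replace=False)
            gt[i, het_cols] = HET
        viol["het_excess"] = list(sel)

        all_chrom.append(chrom_arr)
        all_pos.append(pos)
        all_ref.append(refs.astype(object))
        all_alt.extend(alt_tuples)
        all_gt.append(gt)
        all_depth.append(depth)
        vtypes.extend(vt)
        ilens.extend(il)
        truth.extras.setdefault("violations", {})[chrom] = viol

        if cfg.frac_adjacent > 0:
            # twin sites 1 bp downstream of a sample of emitted sites
            k = int(round(cfg.frac_adjacent * n))
            sel = np.sort(rng.choice(n, size=k, replace=False))
            twin_pos = pos[sel] + 1
            ok = ~np.isin(twin_pos, pos)
            sel, twin_pos = sel[ok], twin_pos[ok]
            all_chrom.append(np.array([chrom] * len(sel), dtype=object))
            all_pos.append(twin_pos)
            all_ref.append(refs[sel].astype(object))
            all_alt.extend([(a,) for a in _NUCS[rng.integers(0, 4, size=len(sel))]])
            all_gt.append(gt[sel])
            all_depth.append(depth[sel])
            vtypes.extend(["SNP"] * len(sel))
            ilens.extend([0] * len(sel))
            truth.extras["violations"][chrom]["adjacent_twins"] = list(twin_pos)

    chrom_cat = np.concatenate(all_chrom)
    pos_cat = np.concatenate(all_pos)
    order = np.lexsort((pos_cat, chrom_cat.astype(str)))
    panel = VariantPanel(
        sample_names,
        chrom_cat[order],
        pos_cat[order],
        np.concatenate(all_ref)[order],
        [all_alt[i] for i in order],
        np.concatenate(all_gt, axis=0)[order],
        np.concatenate(all_depth)[order],
        np.array(vtypes, dtype=object)[order],
        np.array(ilens)[order],
    )
    return PopulationSim(panel, group_of, truth)
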