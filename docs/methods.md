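# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic-data generator does and does not emulate,
and the numerical choices a user may want to revisit.

## Synteny chaining

Blocks are chains of homolog anchors on the *gene-rank* dot plot, not
base-pair coordinates: dot plots of gene order are robust to
intergenic-length variation and make the gap parameter meaningful
(`max_gap_genes` skipped genes, default 25).  Chains must be strictly
monotone in both ranks; orientation is a block property (+/−) and the
strand of individual genes is ignored.  Extraction is greedy
best-chain-first, scored by anchor count, with a fully deterministic
tie-break: longer first, then the lexicographically smallest anchor
sequence, then orientation + before −.  This makes the decomposition
reproducible and checkable against exhaustive enumeration on small
inputs (the test suite does exactly that on a 30-anchor cloud).

Before chaining, tandem redundancy is collapsed: among pairs sharing a
gene whose partners lie within `max_gap_genes` ranks on one partner
chromosome, only the best-scoring pair is kept.  Homolog pairs are
admitted at e-value ≤ 1e-5.  `min_anchors` (default 5) is the smallest
chain reported.  Neither chaining parameter has a canonical published
value; both are exposed in `ChainParams`.

## NG86 counting and Jukes–Cantor correction

Synonymous sites per codon are fractional: at each position, the
fraction of the three single-nucleotide changes that preserve the amino
acid, with changes to stop codons counted as nonsynonymous.  This makes
S + N = 3 × n_codons an exact identity, which the tests rely on.
Differences between codons differing at k positions are averaged over
all k! mutational paths with equal weights; paths through a stop codon
are excluded (if every path is blocked, all paths are used — this
occurs only for unusual pairs and keeps the counts defined).  The
standard genetic code is the default; any NCBI table id can be passed.
Proportions are corrected with d = −(3/4) ln(1 − (4/3)p); p ≥ 3/4 is
reported as saturated rather than clamped.  The 61×61 difference
tables are precomputed per code, so counting long alignments is a
table lookup.

Alignment is out of scope: pairs must arrive codon-aligned and
equal-length (the generator emits them that way).

## Ks mixtures and the two-anchor rate correction

Mixtures are fitted by EM (scikit-learn `GaussianMixture`, 10
initialisations, fixed seed) with k selected by BIC over {1..4} and
components reported mean-sorted; a component with sd < 1e-4 triggers a
reseeded restart.  Values outside (0, ks_max] are discarded first;
`ks_max` defaults to 3.0 because beyond that synonymous sites are
effectively saturated and the tail is noise.  Note that a genuine peak
close to the cap will be truncated and can attract spurious
components — extend `ks_max` when fitting such samples.

Event labels: for the outgroup anchor (grape) the principal (largest
weight) component is the ECH.  For a cucurbit paralog fit, the
oldest (largest-mean) component is the ECH and the largest-weight
remaining component the CCT.  Labelling by age rather than by
proximity to grape's peak avoids circularity: before correction the
lineage's rate, and hence where its ECH "should" sit, is unknown.
For ortholog fits the principal component is the speciation peak.

Correction factors compose sequentially: α_i = e_grape/e_i from the
ECH anchor, then β_i aligning the α-corrected CCT peaks onto the
reference cucurbit's (β = 1 for grape), γ_i = α_iβ_i.  Ortholog Ks
between species i and j is scaled by √(γ_iγ_j) — the geometric mean
treats both lineages symmetrically, since the anchors constrain only
per-lineage paralog scales.  The correction is scale-equivariant:
multiplying a species' sample by λ divides its γ by λ.

## Proto-chromosome inference

The reference genome (the least-rearranged one, chosen by the user) is
segmented at recurrent synteny-patch boundaries: patch edges from
every (counterpart genome, counterpart chromosome) placement of at
least `patch_min` = 20 anchors are clustered within `breakpoint_tol`
= 5 ranks and used to cut each chromosome into atomic segments.

Two voting rules then decide ancestry, both requiring
`min_support` = 2 independent witnesses *and* a strict majority over
contradicting witnesses — the parsimony argument that separates one
event on the reference lineage from coincident independent events on
two counterpart lineages:

* **Split** (rules A/B): adjacent segments of one reference chromosome
  belong to different protos only if enough genomes place them on
  different counterpart chromosomes.  Sharing a chromosome counts as
  "together" regardless of span adjacency, so counterpart or reference
  inversions never split a proto.  Segments with no usable image
  (slivers at ancient junctions) abstain; voting runs between their
  effective neighbours and the sliver joins the nearest one.
* **Link** (rule C): segments of *different* reference chromosomes —
  or non-adjacent segments of the same chromosome, which arise when
  stacked reference events interleave two protos — are merged when
  their images are physically adjacent (counterpart rank gap ≤
  `max_gap_genes`) on a single chromosome in enough genomes.  A WGD
  genome's two subgenome copies are counted as separate witnesses.

Protos are the union-find closure of these decisions, numbered by
reference coordinates.  If two merges compete for one segment the
closure simply joins them; with ≥ 3 informative genomes the majority
condition makes that outcome the parsimonious one.  Counterpart genes
are assigned through their anchors (majority over anchors, then
interpolation of unanchored genes flanked by same-proto neighbours).

The preserved/partite/mosaic classification implements the strict
reciprocal test (τ1 = τ2 = 0.8): a chromosome is *preserved* only if a
near one-to-one image exists in **every** counterpart genome (two
chromosomes allowed for a WGD genome).  Against heavily rearranged
counterparts few chromosomes qualify; this classification is
diagnostic output, and proto inference does not depend on it.

Scenario counting: fusions = Σ_chromosomes (proto segments − 1),
fissions = Σ_protos (chromosomes containing it − expected copies),
where expected copies is 2 when the genome-wide copy ratio ≥
`wgd_ratio_min` = 1.6 flags a lineage WGD.  Runs shorter than
`min_run` = 10 genes are treated as assignment noise and ignored.
The scenario is event-count bookkeeping on the segment decomposition,
not a rearrangement-distance solver: inversions and transpositions are
deliberately invisible to it.

## LTR insertion dating

K2p distances are computed over pairwise-complete ungapped columns;
saturation (either logarithm argument ≤ 0) is flagged and the element
reported "older than datable range" rather than given an extrapolated
age.  The default clock is μ = 4.5e-9 substitutions per site per year;
`calibrate_mu` re-derives it as the median of D/(2T) over orthologous
insertion pairs at a known divergence time (median, not mean, because
ortholog misidentification produces heavy right tails).  Time is kept
in years everywhere; only presentation code divides by 1e6.

A small downward bias (~2%) in cohort median ages is expected at short
LTR lengths: the per-element difference count is integer-valued, and
the median of a binomial sits slightly below its mean at these sizes.

## Variant filtering

Criteria are applied in a fixed order — InDel length (> 5 bp), more
than two alleles, total depth ≤ 150 or ≥ 6570, a neighbouring variant
within 1 bp, homozygous fraction < 0.85 among called genotypes,
heterozygotes > 3 × minor-allele homozygotes — and each dropped site
is attributed to its first failing criterion, so drop counts plus
retained sites always equal the input.  Adjacency is evaluated against
the full input site list and removes both members of a close pair;
since both disappear, the filter is idempotent.  A site with zero
called genotypes falls under the homozygosity criterion.  Total depth
is read from the site-level DP field when present, else summed from
per-sample depths.

## Windowed diversity and the sweep scan

Per site, π = 2c₀c₁/(m(m−1)) from called allele counts; windows
(200 kb, step 20 kb) divide by the full window length in bp, i.e.
windows are assumed fully callable — appropriate for the synthetic
panels and a documented simplification for real callsets.  Watterson's
θ uses S/(a₁L) with n the median number of called allele copies across
the window's sites (missingness varies per site; a single n is needed
for the constants).  Tajima's D uses the standard e₁/e₂ normalisation
and is withheld below `min_snps` = 10 segregating sites, where its
variance estimate is unstable; such windows are reported but excluded
from percentile ranking in the scan.

The scan ranks windows by π_ancestral/π_derived with the denominator
floored at its 1st percentile over non-zero windows — a zero-diversity
window in the derived group is exactly a hard-sweep signature and
should rank at the top, but must not produce infinities.  Candidates
are the intersection of the top `top_ratio_fraction` (10%) of ratios
and the top `top_secondary_fraction` (50%) of a secondary
differentiation score; "top x%" means at or above the linear
interpolated (1−x) quantile.  Candidate windows ≤ 200 kb apart merge
into regions.  The secondary score shipped here is windowed Hudson
F_ST (ratio of sums); it is a surrogate for XP-CLR's composite
likelihood and is labelled as such — an XP-CLR score table on the same
window grid can be passed to `sweep_scan` unchanged.  Because the
selection is percentile-based, a neutral panel still yields
candidates: the expected fraction is the product of the two top
fractions, which the tests bound.

## Synthetic data: what it emulates, and what it does not

The karyotype generator evolves each lineage independently from the
ancestor (a star phylogeny): recurrence across independent descendants
is precisely the evidence the proto-chromosome rules use, so shared
internal branches are not needed for these benchmarks.  WGD is applied
before the branch's other events; fission breakpoints keep both
fragments ≥ `min_segment_genes` = 30 genes so that no undetectably
small chromosome arms are created.  Homolog pairs derive from true
orthology plus 2% spurious pairs with low scores, mimicking
off-diagonal BLAST hits.

Coding-pair divergence is placed entirely at fourfold-degenerate third
positions of codon families whose first two positions are fully
nonsynonymous (Ala/Gly/Pro/Thr/Val), evolving under Jukes–Cantor at
the target Ks.  This makes the NG86+JC estimator exactly consistent —
by construction the benchmark validates counting and correction, not
robustness to codon-usage bias or transition/transversion skew in
coding sequence.

LTR ends evolve independently under K80 with κ = 2, so the expected
end-to-end K2p distance is 2μ·age.

Population panels draw, per group and site, polymorphism indicators
with probability tuned so the group's expected per-bp π hits its
target, with allele frequencies from a symmetric Beta(0.8, 0.8)
spectrum (moment-matched, not a coalescent: no linkage, no shared
drift between groups, no site-frequency-spectrum realism).  Genotypes
are selfing-like (95% drawn as homozygotes), matching an inbred crop
panel; per-site total depths are negative binomial (mean 2200,
shape 10), placing almost all sites inside the depth filter bounds.
Sweeps divide the derived group's polymorphism probability by the
strength (default 10×) inside the region; domestication sweeps affect
landrace and cultivated groups, improvement sweeps only cultivated.
Default group sizes are 13 wild, 16 landrace and 117 cultivated
accessions with π targets 5.9, 1.1 and 0.4 × 10⁻³.

Passing benchmarks on these panels demonstrates that the estimators
and decision rules recover planted truth under the stated model; it
does not demonstrate robustness to linkage disequilibrium, population
structure within groups, reference bias or callset artefacts, all of
which real resequencing data contain.

## Problem sizes

The recovery benchmarks use 20 karyotype simulations of 15
proto-chromosomes × 200 genes across 5 lineages; 500 codon pairs × 300
codons per Ks target; LTR cohorts of 300–500 elements of 400 nt; and
population panels of 4–24 Mb at 0.03 candidate sites/bp with 45–146
samples.  These sizes give the recovery statistics comfortable margins
over their tolerances while keeping a full run in minutes on one CPU.
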