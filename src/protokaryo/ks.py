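"""Ks mixture decomposition and evolutionary-rate correction.

A Ks distribution from intra- or inter-genome collinear gene pairs is a
superposition of bursts of duplicate production (whole-genome events)
and speciation, each smeared by rate variation.  We model the sample
with a Gaussian mixture fitted by EM, select the number of components
by BIC, and take the *principal* (largest-weight) component of an event
as its peak.

Rate correction uses two anchors.  All core eudicots share the ancient
hexaploidy (ECH), with grape the slowest lineage; all cucurbits
additionally share the cucurbit-common tetraploidization (CCT), with
the reference cucurbit (wax gourd) slowest among them.  Stage 1 rescales
every species so its ECH peak matches grape's; stage 2 rescales the
cucurbits so their (stage-1) CCT peaks match the reference cucurbit's.
The combined per-species factor is multiplicative on Ks, and a
cross-species ortholog comparison is scaled by the geometric mean of
the two lineage factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .ng86 import CodonAlignment, ng86_counts
from .synteny import SyntenyBlock

DEFAULT_KS_MAX = 3.0  # saturation guard applied before mixture fitting


@dataclass
class KsMixtureFit:
    comparison_id: str
    components: list[tuple[float, float, float]]  # (weight, mean, sd), sorted by mean
    principal_index: int
    event_labels: dict[int, str] = field(default_factory=dict)
    bic_trace: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    n_values: int = 0

    @property
    def k(self) -> int:
        return len(self.components)

    def peak(self, label: str) -> float:
        """Mean of the component carrying the given event label."""
        for idx, lab in self.event_labels.items():
            if lab == label:
                return self.components[idx][1]
        raise KeyError(
            f"{self.comparison_id}: no component labeled {label!r} "
            f"(have {sorted(self.event_labels.values())})"
        )

    def has_label(self, label: str) -> bool:
        return label in self.event_labels.values()


def fit_ks_mixture(
    ks_values,
    comparison_id: str = "",
    k_range: tuple[int, ...] = (1, 2, 3, 4),
    seed: int = 0,
    ks_max: float = DEFAULT_KS_MAX,
    n_init: int = 10,
    max_restarts: int = 5,
) -> KsMixtureFit:
    """EM-fit a normal mixture to a Ks sample; choose k by BIC.

    Values outside (0, ks_max] are discarded first.  Components are
    returned sorted by mean and the fit is deterministic given ``seed``.
    A degenerate component (sd < 1e-4) triggers a reseeded restart.
    """
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x) & (x > 0) & (x <= ks_max)]
    if len(x) < 50:
        raise ValueError(
            f"{comparison_id or 'ks sample'}: only {len(x)} usable Ks values (<50); "
            "pool more gene pairs before fitting"
        )
    X = x.reshape(-1, 1)
    for attempt in range(max_restarts):
        rs = seed + 1000 * attempt
        best = None
        trace: dict[int, float] = {}
        for k in k_range:
            gm = GaussianMixture(
                n_components=k, covariance_type="full", n_init=n_init,
                random_state=rs, reg_covar=1e-6,
            ).fit(X)
            bic = gm.bic(X)
            trace[k] = float(bic)
            if best is None or bic < best[0]:
                best = (bic, k, gm)
        _, k, gm = best
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.reshape(-1))
        weights = gm.weights_.ravel()
        if sds.min() >= 1e-4:
            order = np.argsort(means)
            comps = [(float(weights[i]), float(means[i]), float(sds[i])) for i in order]
            principal = int(np.argmax([c[0] for c in comps]))
            return KsMixtureFit(comparison_id, comps, principal, {}, trace, seed, len(x))
    raise RuntimeError(
        f"{comparison_id}: EM produced a degenerate component in {max_restarts} restarts"
    )


def label_paralog_fit(fit: KsMixtureFit, is_outgroup_anchor: bool) -> KsMixtureFit:
    """Attach WGD event labels to an intra-genome (paralog) Ks fit.

    For the outgroup anchor (grape) the principal component represents
    the ECH.  For a cucurbit, the oldest (largest-mean) component is the
    ECH and the largest-weight remaining component is the CCT; any other
    components are labeled "other".
    """
    labels: dict[int, str] = {}
    if is_outgroup_anchor:
        labels[fit.principal_index] = "ECH"
    else:
        if fit.k < 2:
            raise ValueError(
                f"{fit.comparison_id}: cucurbit paralog fit needs >=2 components "
                "(ECH and CCT), got 1"
            )
        ech = fit.k - 1  # components are mean-sorted
        labels[ech] = "ECH"
        rest = [i for i in range(fit.k) if i != ech]
        cct = max(rest, key=lambda i: fit.components[i][0])
        labels[cct] = "CCT"
    for i in range(fit.k):
        labels.setdefault(i, "other")
    fit.event_labels = labels
    return fit


def label_ortholog_fit(fit: KsMixtureFit) -> KsMixtureFit:
    """The principal component of a between-species fit is the speciation peak."""
    labels = {i: "other" for i in range(fit.k)}
    labels[fit.principal_index] = "speciation"
    fit.event_labels = labels
    return fit


@dataclass
class RateCorrection:
    """Two-anchor multiplicative Ks corrections.

    ``alpha`` aligns each species' ECH peak onto grape's; ``beta``
    aligns the cucurbits' stage-1 CCT peaks onto the reference
    cucurbit's; ``gamma = alpha * beta`` is the combined factor applied
    to a species' paralog Ks values.
    """

    grape: str
    reference: str
    ech_peaks: dict[str, float]
    cct_peaks: dict[str, float]
    alpha: dict[str, float]
    beta: dict[str, float]
    gamma: dict[str, float]

    def gamma_pair(self, sp_i: str, sp_j: str) -> float:
        """Factor for an ortholog comparison: geometric mean of the two lineages."""
        return math.sqrt(self.gamma[sp_i] * self.gamma[sp_j])

    def apply(self, species: str, ks_values):
        return np.asarray(ks_values, dtype=float) * self.gamma[species]


def correct_evolution_rates(
    paralog_fits: dict[str, KsMixtureFit],
    grape: str,
    reference: str,
) -> RateCorrection:
    """Derive per-species correction factors from labeled paralog fits.

    Every fit must carry an ECH label; every species other than the
    grape anchor must also carry a CCT label.  By construction the
    grape factor is its alpha (beta = 1) and the reference cucurbit's
    CCT peak maps onto itself.
    """
    if grape not in paralog_fits:
        raise KeyError(f"no paralog fit supplied for the grape anchor {grape!r}")
    if reference not in paralog_fits:
        raise KeyError(f"no paralog fit supplied for the reference cucurbit {reference!r}")
    ech: dict[str, float] = {}
    cct: dict[str, float] = {}
    for sp, fit in paralog_fits.items():
        if not fit.has_label("ECH"):
            raise ValueError(f"species {sp!r}: fit has no labeled ECH component")
        ech[sp] = fit.peak("ECH")
        if sp != grape:
            if not fit.has_label("CCT"):
                raise ValueError(f"species {sp!r}: fit has no labeled CCT component")
            cct[sp] = fit.peak("CCT")
    alpha = {sp: ech[grape] / ech[sp] for sp in paralog_fits}
    ref_cct_corrected = alpha[reference] * cct[reference]
    beta = {}
    for sp in paralog_fits:
        if sp == grape:
            beta[sp] = 1.0
        else:
            beta[sp] = ref_cct_corrected / (alpha[sp] * cct[sp])
    gamma = {sp: alpha[sp] * beta[sp] for sp in paralog_fits}
    return RateCorrection(grape, reference, ech, cct, alpha, beta, gamma)


# ---------------------------------------------------------------------------
# per-block Ks summaries
# ---------------------------------------------------------------------------


def block_median_ks(
    block: SyntenyBlock,
    cds_a: dict[str, str],
    cds_b: dict[str, str],
    table_id: int = 1,
) -> SyntenyBlock:
    """Attach the median anchor Ks to a syntenic block.

    Anchors with saturated or undefined Ks are excluded from the
    median; anchors whose CDS is missing are skipped.  At least half
    the anchors must have a CDS on both sides.
    """
    values = []
    n_with_cds = 0
    for _, _, ga, gb in block.anchors:
        sa, sb = cds_a.get(ga), cds_b.get(gb)
        if sa is None or sb is None:
            continue
        n_with_cds += 1
        if len(sa) != len(sb):
            continue
        counts = ng86_counts(CodonAlignment(ga, gb, sa, sb), table_id)
        if np.isfinite(counts.Ks):
            values.append(counts.Ks)
    if n_with_cds * 2 < block.n_anchors:
        raise ValueError(
            f"block {block.block_id}: CDS available for only {n_with_cds}/"
            f"{block.n_anchors} anchors"
        )
    if values:
        block.median_ks = float(np.median(values))
    else:
        import warnings

        warnings.warn(f"block {block.block_id}: no finite anchor Ks; median left unset")
        block.median_ks = None
    return block
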