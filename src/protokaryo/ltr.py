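"""Molecular-clock dating of LTR retrotransposon insertions.

The two long terminal repeats of a retroelement are identical at the
moment of insertion and diverge afterwards, so the Kimura two-parameter
distance D between the 5' and 3' LTR dates the insertion via
T = D / (2 mu), with mu the substitution rate per site per year.  The
default rate is 4.5e-9, and :func:`calibrate_mu` re-derives it from
orthologous insertions shared by two species of known divergence time
(mu = D / 2T, aggregated as the median over pairs).

Sequences are expected pre-aligned; gapped or ambiguous columns are
dropped pairwise-complete.  Years are the unit throughout — convert to
MYA only for presentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MU = 4.5e-9  # substitutions / site / year

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    D: float  # nan when saturated
    n_sites: int
    saturated: bool = False


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance over the ungapped columns of an alignment.

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q); saturation (either log
    argument <= 0) is flagged and D left undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ ({len(seq_a)} vs {len(seq_b)})")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no ungapped, unambiguous columns in the alignment")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P, Q, float("nan"), n, saturated=True)
    D = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(P, Q, float(D), n, saturated=False)


def k2p_kappa(P: float, Q: float) -> float:
    """Transition/transversion rate ratio implied by pooled P and Q."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    D = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    beta_t = -0.25 * np.log(w2)
    alpha_t = D - 2.0 * beta_t
    return float(alpha_t / beta_t) if beta_t > 0 else float("inf")


@dataclass
class LTRElement:
    element_id: str
    chrom: str
    start: int
    end: int
    superfamily: str = "unknown"  # Copia / Gypsy / unknown
    ltr5_seq: str = ""
    ltr3_seq: str = ""
    D: float = float("nan")
    T: float = float("nan")  # years
    saturated: bool = False


@dataclass
class ClockCalibration:
    mu: float
    source: str  # "fixed" | "calibrated"
    calibration_pairs: int = 0
    divergence_time_years: float = float("nan")
    d_dispersion: float = float("nan")  # MAD of per-pair D

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


FIXED_CLOCK = ClockCalibration(mu=DEFAULT_MU, source="fixed")


def calibrate_mu(
    ortho_pairs: list[tuple[str, str]], divergence_time_years: float
) -> ClockCalibration:
    """Infer mu from orthologous insertions at a known species divergence.

    Each pair contributes mu_i = D_i / (2 T); the calibration takes the
    median over pairs for robustness to misidentified orthologs, and
    reports the number of usable pairs and the dispersion of D.
    """
    if divergence_time_years <= 0:
        raise ValueError("divergence_time_years must be positive")
    if not ortho_pairs:
        raise ValueError("at least one orthologous pair is required")
    ds = []
    for a, b in ortho_pairs:
        res = k2p_distance(a, b)
        if not res.saturated:
            ds.append(res.D)
    if not ds:
        raise ValueError("all calibration pairs are saturated; cannot estimate mu")
    ds = np.asarray(ds)
    mu = float(np.median(ds) / (2.0 * divergence_time_years))
    mad = float(np.median(np.abs(ds - np.median(ds))))
    return ClockCalibration(mu, "calibrated", len(ds), divergence_time_years, mad)


def insertion_time(element: LTRElement, cal: ClockCalibration = FIXED_CLOCK) -> LTRElement:
    """Date one element: T = D / (2 mu), stored on the element in years."""
    if not np.isfinite(element.D):
        res = k2p_distance(element.ltr5_seq, element.ltr3_seq)
        element.D = res.D
        element.saturated = res.saturated
    if element.saturated or not np.isfinite(element.D):
        element.T = float("nan")
        warnings.warn(
            f"{element.element_id}: LTR divergence saturated; older than datable range"
        )
        return element
    element.T = element.D / (2.0 * cal.mu)
    return element


def date_elements(
    elements: list[LTRElement], cal: ClockCalibration = FIXED_CLOCK
) -> list[LTRElement]:
    return [insertion_time(e, cal) for e in elements]


def insertion_profile(
    elements: list[LTRElement], bin_width_years: float = 1e6
) -> pd.DataFrame:
    """Histogram of insertion times per superfamily.

    Bins cover [0, max T]; one row per (superfamily, bin) including
    zero-count rows, so the profile can be plotted directly.
    """
    dated = [e for e in elements if np.isfinite(e.T)]
    if not dated:
        raise ValueError("no dated elements to profile")
    tmax = max(e.T for e in dated)
    n_bins = max(1, int(np.ceil((tmax + 1e-9) / bin_width_years)))
    edges = np.arange(n_bins + 1) * bin_width_years
    fams = sorted({e.superfamily for e in dated})
    rows = []
    for fam in fams:
        ts = np.array([e.T for e in dated if e.superfamily == fam])
        counts, _ = np.histogram(ts, bins=edges)
        for i, c in enumerate(counts):
            rows.append((fam, edges[i], edges[i + 1], int(c)))
    return pd.DataFrame(rows, columns=["superfamily", "t_lo_years", "t_hi_years", "count"])


# ---------------------------------------------------------------------------
# I/O: elements TSV + FASTA of end pairs (IDs <element>_5p / <element>_3p)
# ---------------------------------------------------------------------------


def load_elements(tsv_path: str | Path, fasta_path: str | Path) -> list[LTRElement]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t")
    out = []
    for r in df.itertuples():
        eid = str(r.element_id)
        try:
            l5, l3 = seqs[f"{eid}_5p"], seqs[f"{eid}_3p"]
        except KeyError as exc:
            raise KeyError(f"LTR end sequence {exc.args[0]!r} missing from FASTA") from None
        out.append(
            LTRElement(eid, str(r.chrom), int(r.start), int(r.end),
                       str(r.superfamily), l5, l3)
        )
    return out


def write_elements(elements: list[LTRElement], tsv_path, fasta_path=None) -> None:
    rows = [
        (e.element_id, e.chrom, e.start, e.end, e.superfamily, e.D, e.T, e.saturated)
        for e in elements
    ]
    pd.DataFrame(
        rows, columns=["element_id", "chrom", "start", "end", "superfamily",
                       "D", "T_years", "saturated"]
    ).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for e in elements:
                fh.write(f">{e.element_id}_5p\n{e.ltr5_seq}\n>{e.element_id}_3p\n{e.ltr3_seq}\n")


def write_calibration(cal: ClockCalibration, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"mu": cal.mu, "source": cal.source, "calibration_pairs": cal.calibration_pairs,
             "divergence_time_years": cal.divergence_time_years,
             "d_dispersion": cal.d_dispersion},
            fh, indent=2,
        )
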