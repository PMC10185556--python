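"""Transcription-factor / methylation mediation analyses.

For TF binding motifs discovered around sentinel sites (motif occurrences
arrive as intervals from an external scanner), three questions are asked:
does TF expression correlate with sentinel methylation; does adjusting
the TF-to-target-gene association for sentinel methylation attenuate it
(a mediation contrast, both fits sharing the random-intercept machinery
of the methylation-expression model); and are CG dinucleotides enriched
at specific offsets within the motif relative to its +-150 bp flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import fit_random_intercept

FLANK = 150


@dataclass
class MotifOccurrence:
    motif: str
    chrom: str
    start: int
    end: int
    strand: str
    sentinel: str = ""
    contains_cg: bool = False

    def __post_init__(self):
        if self.end - self.start > 2 * FLANK + 1:
            raise ValueError("occurrence wider than the sentinel +-150 bp scan region")


@dataclass
class MediationResult:
    tf: str
    sentinel: str
    target: str
    beta_unadjusted: float
    beta_adjusted: float
    se_unadjusted: float
    se_adjusted: float
    delta: float
    proportion_change: float
    n: int
    skipped: str = ""


def tf_sentinel_correlation(tf_expr, sentinel_meth) -> tuple[float, float]:
    """Pearson correlation between TF expression and sentinel methylation
    across aligned samples (pairwise-complete, >= 10 pairs)."""
    x = np.asarray(tf_expr, dtype=float)
    y = np.asarray(sentinel_meth, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 10:
        raise ValueError("need >= 10 complete pairs")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def mediation_contrast(tf_expr, target_expr, sentinel_meth, participants,
                       covars: pd.DataFrame | None = None,
                       tf: str = "tf", sentinel: str = "sentinel",
                       target: str = "target") -> MediationResult:
    """TF-to-target association without and with sentinel-methylation
    adjustment, both with a per-participant random intercept on the same
    sample subset.

    delta = beta_unadjusted - beta_adjusted; the proportion change
    delta / beta_unadjusted is NaN-flagged when the unadjusted effect is
    numerically zero.  If methylation is collinear with TF expression
    (r^2 > 0.99) the adjusted fit is skipped and flagged.
    """
    x = np.asarray(tf_expr, dtype=float)
    yv = np.asarray(target_expr, dtype=float)
    mv = np.asarray(sentinel_meth, dtype=float)
    part = np.asarray(participants)
    ok = ~(np.isnan(x) | np.isnan(yv) | np.isnan(mv))
    if covars is not None:
        ok &= ~covars.isna().any(axis=1).to_numpy()
    x, yv, mv, part = x[ok], yv[ok], mv[ok], part[ok]

    base = pd.DataFrame({"intercept": 1.0, "tf": x})
    if covars is not None:
        base = pd.concat([base, covars[ok].reset_index(drop=True)], axis=1)
    fit0 = fit_random_intercept(yv, base, part)

    r = np.corrcoef(x, mv)[0, 1] if np.std(mv) > 0 and np.std(x) > 0 else 1.0
    if r * r > 0.99:
        return MediationResult(tf, sentinel, target,
                               float(fit0.params["tf"]), np.nan,
                               float(fit0.bse["tf"]), np.nan,
                               np.nan, np.nan, int(ok.sum()),
                               skipped="meth_collinear_with_tf")
    adj = base.assign(meth=mv)
    fit1 = fit_random_intercept(yv, adj, part)
    b0, b1 = float(fit0.params["tf"]), float(fit1.params["tf"])
    delta = b0 - b1
    prop = delta / b0 if abs(b0) >= 1e-6 else np.nan
    return MediationResult(tf, sentinel, target, b0, b1,
                           float(fit0.bse["tf"]), float(fit1.bse["tf"]),
                           delta, prop, int(ok.sum()))


def motif_cg_profile(motifs: list[MotifOccurrence], cg_positions: dict[str, np.ndarray],
                     flank: int = FLANK) -> np.ndarray:
    """Count CG dinucleotide positions at each offset in [-flank, +flank]
    around motif centres, orientation-corrected for minus-strand
    occurrences.

    ``cg_positions`` maps chromosome to sorted 0-based CG (cytosine)
    positions.  Returns a vector of length 2*flank + 1; its sum equals
    the number of (occurrence, CG) pairs within range.
    """
    profile = np.zeros(2 * flank + 1, dtype=int)
    for occ in motifs:
        pos = np.asarray(cg_positions.get(occ.chrom, ()), dtype=int)
        if pos.size == 0:
            continue
        centre = (occ.start + occ.end - 1) // 2
        off = pos - centre
        if occ.strand == "-":
            off = -off
        off = off[(off >= -flank) & (off <= flank)]
        np.add.at(profile, off + flank, 1)
    return profile
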