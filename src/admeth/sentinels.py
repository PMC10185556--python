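"""Sentinel definition, DMR extension and exact binomial sign tests.

Epigenome-wide significant sites are collapsed into loci by single-linkage
chaining (sites on one chromosome joined when <= 5 kb apart), the lowest
p-value member of each locus is its sentinel, and sentinels are annotated
as differentially methylated regions (DMRs) when at least five flanking
sites within +-5 kb associate in the same direction after Bonferroni
adjustment.

The exact binomial test is computed with log-space tail summation so that
sign-test p-values far below the double-precision underflow threshold
(~1e-308) remain exact in the log domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "SentinelLocus",
    "DMRAnnotation",
    "exact_binomial",
    "log_binomial_tail",
    "clump_loci",
    "extend_dmr",
    "annotate_dmrs",
    "depot_concordance",
]


# ---------------------------------------------------------------------------
# exact binomial
# ---------------------------------------------------------------------------

def _log_pmf(i: np.ndarray, n: int, p0: float) -> np.ndarray:
    return (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * math.log(p0) + (n - i) * math.log1p(-p0)
    )


def log_binomial_tail(k: int, n: int, p0: float, upper: bool = True) -> float:
    """Natural log of P(X >= k) (or P(X <= k)) for X ~ Binomial(n, p0).

    Exact log-space summation of the pmf over the tail; accurate for
    tails far below the double-precision underflow limit.
    """
    if upper:
        i = np.arange(k, n + 1)
    else:
        i = np.arange(0, k + 1)
    if i.size == 0:
        return -math.inf
    return float(logsumexp(_log_pmf(i, n, p0)))


def exact_binomial(k: int, n: int, p0: float = 0.5, sided: str = "one",
                   log: bool = False) -> float:
    """Exact binomial test p-value.

    One-sided is the upper-tail probability P(X >= k).  Two-sided doubles
    the smaller tail and caps at 1 (at p0 = 0.5 this equals the
    minimum-likelihood rule used by R's binom.test, by symmetry).

    With ``log=True`` the natural log of the p-value is returned, which
    stays exact when the p-value itself underflows a double.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0,1)")
    if sided == "one":
        logp = log_binomial_tail(k, n, p0, upper=True)
    elif sided == "two":
        lo = log_binomial_tail(k, n, p0, upper=False)
        hi = log_binomial_tail(k, n, p0, upper=True)
        logp = min(lo, hi) + math.log(2.0)
        logp = min(logp, 0.0)  # cap at 1
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return logp if log else math.exp(logp)


# ---------------------------------------------------------------------------
# locus clumping
# ---------------------------------------------------------------------------

@dataclass
class SentinelLocus:
    sentinel: str
    members: list[str]
    chrom: str
    span: int
    p: float
    effect: float
    start: int = 0  # 0-based position of the sentinel site


@dataclass
class DMRAnnotation:
    sentinel: str
    n_consistent: int
    width: int
    member_positions: list[int] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    is_dmr: bool = False


def clump_loci(sig_sites: pd.DataFrame, max_gap: int = 5000,
               mode: str = "chain") -> list[SentinelLocus]:
    """Collapse significant sites into loci and pick sentinels.

    ``sig_sites`` is indexed by site id with columns chrom, start, p,
    effect.  mode='chain' (default) joins sites on the same chromosome
    whenever consecutive sites are <= max_gap apart (single-linkage
    closure, so a chain's ends may be further apart than max_gap);
    mode='window' greedily takes the lowest-p site as a sentinel and
    absorbs all sites within max_gap of it.

    The sentinel is the member with the lowest p; ties break to the lower
    genomic position.
    """
    loci: list[SentinelLocus] = []
    if sig_sites.empty:
        return loci

    def _make(sub: pd.DataFrame) -> SentinelLocus:
        best = sub.sort_values(["p", "start"], kind="mergesort").iloc[0]
        return SentinelLocus(
            sentinel=str(best.name),
            members=sorted(sub.index),
            chrom=str(best["chrom"]),
            span=int(sub["start"].max() - sub["start"].min()),
            p=float(best["p"]),
            effect=float(best["effect"]),
            start=int(best["start"]),
        )

    for chrom, sub in sig_sites.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        if mode == "chain":
            gaps = np.diff(sub["start"].to_numpy())
            breaks = np.flatnonzero(gaps > max_gap)
            pieces = np.split(np.arange(len(sub)), breaks + 1)
            for piece in pieces:
                loci.append(_make(sub.iloc[piece]))
        elif mode == "window":
            remaining = sub.copy()
            while not remaining.empty:
                best = remaining.sort_values(["p", "start"], kind="mergesort").iloc[0]
                near = (remaining["start"] - best["start"]).abs() <= max_gap
                loci.append(_make(remaining[near]))
                remaining = remaining[~near]
        else:
            raise ValueError("mode must be 'chain' or 'window'")
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


# ---------------------------------------------------------------------------
# DMR extension
# ---------------------------------------------------------------------------

def extend_dmr(sentinel: SentinelLocus, all_sites: pd.DataFrame,
               min_flank: int = 5, window: int = 5000,
               bonferroni_n: int | None = None) -> DMRAnnotation:
    """Annotate a sentinel as a DMR if >= min_flank sites within +-window
    share its direction of effect at Bonferroni-adjusted p < 0.05.

    ``all_sites`` must contain every analysed site (not just significant
    ones), indexed by site id with columns chrom, start, p, effect.  The
    Bonferroni denominator defaults to the number of sites inside this
    sentinel's window; `annotate_dmrs` passes the pooled denominator over
    all tested windows instead.
    """
    if sentinel.sentinel not in all_sites.index:
        raise ValueError(f"sentinel {sentinel.sentinel!r} absent from all_sites")
    d = all_sites[all_sites["chrom"] == sentinel.chrom]
    near = d[(d["start"] - sentinel.start).abs() <= window]
    flank = near.drop(index=sentinel.sentinel, errors="ignore")
    denom = bonferroni_n if bonferroni_n is not None else max(len(flank), 1)
    ok = (np.sign(flank["effect"]) == np.sign(sentinel.effect)) & \
         (flank["p"] < 0.05 / denom)
    consistent = flank[ok]
    members = sorted(set(consistent.index) | {sentinel.sentinel})
    positions = sorted(int(all_sites.loc[m, "start"]) for m in members)
    return DMRAnnotation(
        sentinel=sentinel.sentinel,
        n_consistent=int(ok.sum()),
        width=positions[-1] - positions[0] if len(positions) > 1 else 0,
        member_positions=positions,
        members=members,
        is_dmr=bool(ok.sum() >= min_flank),
    )


def annotate_dmrs(sentinels: list[SentinelLocus], all_sites: pd.DataFrame,
                  min_flank: int = 5, window: int = 5000) -> list[DMRAnnotation]:
    """DMR-annotate every sentinel with a shared Bonferroni denominator:
    the number of array sites falling in any tested +-window (sentinels
    themselves excluded)."""
    denom = 0
    for s in sentinels:
        d = all_sites[all_sites["chrom"] == s.chrom]
        near = (d["start"] - s.start).abs() <= window
        denom += int(near.sum()) - int(s.sentinel in d.index[near])
    denom = max(denom, 1)
    return [extend_dmr(s, all_sites, min_flank, window, bonferroni_n=denom)
            for s in sentinels]


# ---------------------------------------------------------------------------
# cross-depot concordance
# ---------------------------------------------------------------------------

def depot_concordance(sentinels_a: list[SentinelLocus], results_b: pd.DataFrame,
                      alpha: float = 0.05) -> dict:
    """Direction concordance of depot-A sentinels in depot-B results.

    Counts sentinels (i) direction-consistent in B and (ii) additionally
    at p < alpha / N_sentinels (Bonferroni), and tests (i) against a fair
    coin with the two-sided exact binomial test.  Sentinels missing from
    B are dropped from the denominator.
    """
    present = [s for s in sentinels_a if s.sentinel in results_b.index]
    n_missing = len(sentinels_a) - len(present)
    n = len(present)
    if n == 0:
        return {"n": 0, "n_missing": n_missing, "n_consistent": 0,
                "n_consistent_significant": 0, "p": 1.0}
    thresh = alpha / n
    k_cons = 0
    k_sig = 0
    for s in present:
        row = results_b.loc[s.sentinel]
        same = np.sign(row["effect"]) == np.sign(s.effect)
        k_cons += bool(same)
        k_sig += bool(same and row["p"] < thresh)
    return {
        "n": n,
        "n_missing": n_missing,
        "n_consistent": k_cons,
        "n_consistent_significant": k_sig,
        "p": exact_binomial(k_cons, n, 0.5, sided="two"),
    }
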