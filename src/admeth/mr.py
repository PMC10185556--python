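"""Two-sample Mendelian randomisation of sentinel methylation on
GWAS phenotypes.

Instruments come from a cis-mQTL scan (SNPs within +-500 kb of the
sentinel regressed on methylation, strand-ambiguous palindromic SNPs
with MAF > 0.42 removed), pruned by greedy LD clumping and gated at
Bonferroni-corrected p < 0.05.  Causal estimates use the Wald ratio for
a single instrument, inverse-variance-weighted (IVW) regression through
the origin for several, and MR-Egger (slope + pleiotropy intercept) for
three or more; the Steiger test orients causality by comparing the
variance the instrument explains in exposure vs outcome.  A locus is
flagged causal when both the MR and the Steiger tests pass FDR < 0.01
with an exposure-to-outcome direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, GWASSummary, MethylationMatrix
from .ewas import bh_fdr

logger = logging.getLogger(__name__)

CIS_WINDOW = 500_000
PALINDROME_MAF = 0.42

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MQTLRecord:
    snp: str
    site: str
    beta: float          # methylation beta units per effect allele
    se: float
    p: float
    r2: float            # variance of methylation explained
    distance: int        # signed bp, SNP minus site
    effect_allele: str = "A"
    other_allele: str = "G"
    n: int = 0


@dataclass
class MRResult:
    site: str
    trait: str
    method: str                       # wald | ivw | egger
    beta: float
    se: float
    p: float
    n_snps: int
    q: float = math.nan
    steiger_direction: str = ""       # exposure->outcome | outcome->exposure
    steiger_p: float = math.nan
    cochran_q: float = math.nan
    q_p: float = math.nan
    egger_intercept: float = math.nan
    egger_intercept_p: float = math.nan
    snps: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# instrument discovery
# ---------------------------------------------------------------------------

def mqtl_scan(g: GenotypeMatrix, m: MethylationMatrix, site: str,
              window: int = CIS_WINDOW, covars: pd.DataFrame | None = None) -> list[MQTLRecord]:
    """Cis-SNP scan: OLS of (optionally covariate-adjusted) methylation at
    ``site`` on dosage for every SNP within the window, after removing
    ambiguous palindromic SNPs with MAF > PALINDROME_MAF."""
    srow = m.sites.loc[site]
    in_win = (g.snps["chrom"] == srow["chrom"]) & \
             ((g.snps["start"] - srow["start"]).abs() <= window)
    drop = g.is_palindromic() & (g.maf > PALINDROME_MAF)
    snp_ids = g.snp_ids[in_win & ~drop]
    if len(snp_ids) == 0:
        logger.info("mqtl_scan: no in-window SNPs for site %s", site)
        return []
    shared = [s for s in m.betas.columns if s in g.dosages.columns]
    y = m.betas.loc[site, shared].to_numpy(dtype=float)
    if covars is not None:
        C = covars.reindex(shared).to_numpy(dtype=float)
        Xc = np.column_stack([np.ones(len(shared)), C])
        y = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    out = []
    for snp in snp_ids:
        x = g.dosages.loc[snp, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 4 or np.var(x[ok]) == 0:
            continue
        res = stats.linregress(x[ok], y[ok])
        t2 = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
        r2 = t2 / (t2 + n - 2)
        out.append(MQTLRecord(
            snp=snp, site=site, beta=float(res.slope), se=float(res.stderr),
            p=float(res.pvalue), r2=float(r2),
            distance=int(g.snps.loc[snp, "start"] - srow["start"]),
            effect_allele=g.snps.loc[snp, "effect_allele"],
            other_allele=g.snps.loc[snp, "other_allele"], n=n))
    return out


def ld_clump(records: list[MQTLRecord], g: GenotypeMatrix,
             r2_max: float = 0.01) -> list[MQTLRecord]:
    """Greedy LD pruning: walk records by ascending p, keep a SNP iff its
    dosage r-squared with every kept SNP is below r2_max.  Monomorphic
    SNPs have undefined r2 and are treated as independent (flagged)."""
    ordered = sorted(records, key=lambda r: (r.p, r.snp))
    kept: list[MQTLRecord] = []
    dos = {r.snp: g.dosages.loc[r.snp].to_numpy(dtype=float) for r in records}
    for rec in ordered:
        x = dos[rec.snp]
        independent = True
        for other in kept:
            yv = dos[other.snp]
            if np.std(x) == 0 or np.std(yv) == 0:
                logger.info("ld_clump: monomorphic SNP %s or %s, treated independent",
                            rec.snp, other.snp)
                continue
            r = np.corrcoef(x, yv)[0, 1]
            if r * r >= r2_max:
                independent = False
                break
        if independent:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# harmonisation and estimators
# ---------------------------------------------------------------------------

def harmonise(instr: MQTLRecord, outcome: pd.Series) -> tuple[float, float]:
    """Align an outcome GWAS row to the instrument's effect allele.

    Returns (beta_out, se_out) on the instrument's allele orientation;
    raises on allele sets that cannot be reconciled.
    """
    ea, oa = instr.effect_allele, instr.other_allele
    oea, ooa = str(outcome["effect_allele"]), str(outcome["other_allele"])
    if (oea, ooa) == (ea, oa):
        return float(outcome["beta"]), float(outcome["se"])
    if (oea, ooa) == (oa, ea):
        return -float(outcome["beta"]), float(outcome["se"])
    # strand flip
    if (_COMP.get(oea), _COMP.get(ooa)) == (ea, oa):
        return float(outcome["beta"]), float(outcome["se"])
    if (_COMP.get(oea), _COMP.get(ooa)) == (oa, ea):
        return -float(outcome["beta"]), float(outcome["se"])
    raise ValueError(
        f"cannot harmonise alleles for {instr.snp}: exposure {ea}/{oa} vs outcome {oea}/{ooa}")


def wald_ratio(instr: MQTLRecord, outcome: pd.Series, trait: str = "trait") -> MRResult:
    """Single-instrument causal estimate: beta_out / beta_exp with the
    first-order se_out / |beta_exp| standard error."""
    if abs(instr.beta) < 1e-12:
        raise ValueError(f"exposure effect for {instr.snp} is numerically zero")
    b_out, se_out = harmonise(instr, outcome)
    beta = b_out / instr.beta
    se = se_out / abs(instr.beta)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MRResult(site=instr.site, trait=trait, method="wald", beta=beta,
                    se=se, p=float(p), n_snps=1, snps=[instr.snp])


def ivw_mr(instrs: list[MQTLRecord], outcome: pd.DataFrame, trait: str = "trait",
           effects: str = "fixed") -> MRResult:
    """IVW estimate: weighted regression of outcome betas on exposure
    betas through the origin with weights 1/se_out^2.  Random effects use
    the multiplicative model, inflating the se by sqrt(Q/df) floored
    at 1."""
    if len(instrs) < 2:
        raise ValueError("IVW needs >=2 instruments; use wald_ratio")
    bx = np.array([i.beta for i in instrs])
    pairs = [harmonise(i, outcome.loc[i.snp]) for i in instrs]
    by = np.array([p[0] for p in pairs])
    se_y = np.array([p[1] for p in pairs])
    w = 1.0 / se_y**2
    beta = float((w * bx * by).sum() / (w * bx * bx).sum())
    se = float(1.0 / math.sqrt((w * bx * bx).sum()))
    Q = float((w * (by - beta * bx) ** 2).sum())
    df = len(instrs) - 1
    if effects == "random":
        se *= max(1.0, math.sqrt(Q / df))
    elif effects != "fixed":
        raise ValueError("effects must be fixed or random")
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MRResult(site=instrs[0].site, trait=trait, method="ivw", beta=beta,
                    se=se, p=float(p), n_snps=len(instrs),
                    cochran_q=Q, q_p=float(stats.chi2.sf(Q, df)),
                    snps=[i.snp for i in instrs])


def egger_mr(instrs: list[MQTLRecord], outcome: pd.DataFrame,
             trait: str = "trait") -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    intercept, exposure effects oriented non-negative; the intercept and
    its p-value quantify directional pleiotropy.  Standard errors use the
    multiplicative random-effects convention (scale floored at 1)."""
    if len(instrs) < 3:
        raise ValueError("MR-Egger needs >=3 instruments")
    bx = np.array([i.beta for i in instrs])
    pairs = [harmonise(i, outcome.loc[i.snp]) for i in instrs]
    by = np.array([p[0] for p in pairs])
    se_y = np.array([p[1] for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    A = X.T @ WX
    coef = np.linalg.solve(A, WX.T @ by)
    resid = by - X @ coef
    df = len(instrs) - 2
    scale = max(1.0, float((w * resid**2).sum() / df))
    cov = np.linalg.inv(A) * scale
    se = np.sqrt(np.diag(cov))
    Q = float((w * resid**2).sum())
    p_slope = 2 * stats.t.sf(abs(coef[1]) / se[1], df)
    p_int = 2 * stats.t.sf(abs(coef[0]) / se[0], df)
    return MRResult(site=instrs[0].site, trait=trait, method="egger",
                    beta=float(coef[1]), se=float(se[1]), p=float(p_slope),
                    n_snps=len(instrs), cochran_q=Q,
                    q_p=float(stats.chi2.sf(Q, df)),
                    egger_intercept=float(coef[0]), egger_intercept_p=float(p_int),
                    snps=[i.snp for i in instrs])


def steiger_test(r2_exposure: float, n_exposure: int, r2_outcome: float,
                 n_outcome: int) -> tuple[str, float]:
    """Directionality: compare instrument-exposure and instrument-outcome
    correlations via Fisher's z for independent samples.

    direction is exposure->outcome iff r2_exposure > r2_outcome; the
    two-sided p tests whether the two correlations differ.
    """
    for r2 in (r2_exposure, r2_outcome):
        if not (0 <= r2 < 1):
            raise ValueError("r2 must be in [0,1)")
    if min(n_exposure, n_outcome) < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (math.atanh(math.sqrt(r2_exposure)) - math.atanh(math.sqrt(r2_outcome))) / \
        math.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    p = 2 * stats.norm.sf(abs(z))
    direction = "exposure->outcome" if r2_exposure > r2_outcome else "outcome->exposure"
    return direction, float(p)


def outcome_r2(beta: float, se: float, n: int) -> float:
    """Variance explained implied by a GWAS beta/se at sample size n,
    via the t-statistic identity r2 = t^2 / (t^2 + n - 2)."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


# ---------------------------------------------------------------------------
# pipeline and proxies
# ---------------------------------------------------------------------------

def mr_pipeline(sentinel_sites: list[str], g: GenotypeMatrix, m: MethylationMatrix,
                gwas_traits: list[GWASSummary], covars: pd.DataFrame | None = None,
                clump_r2: float = 0.01, q_threshold: float = 0.01,
                sensitivity_r2: float = 0.8) -> pd.DataFrame:
    """Per sentinel x trait MR with instrument selection, Steiger gating
    and a correlated-instrument sensitivity pass.

    Instruments: cis-mQTLs clumped at r2 < clump_r2 and associated at
    Bonferroni-corrected p < 0.05 (denominator = in-window SNPs tested for
    that sentinel).  Wald ratio or IVW by instrument count; BH q-values
    across all (sentinel, trait) tests per method family; flagged causal
    when q_MR < q_threshold and q_Steiger < q_threshold with an
    exposure->outcome direction.  Where >=3 correlated instruments exist
    (clump at r2 < sensitivity_r2) IVW and Egger sensitivity estimates
    are appended with method suffix "_sens".
    """
    scans: dict[str, list[MQTLRecord]] = {}
    n_tested: dict[str, int] = {}
    for site in sentinel_sites:
        recs = mqtl_scan(g, m, site, covars=covars)
        scans[site] = recs
        n_tested[site] = len(recs)

    rows: list[MRResult] = []
    untestable: list[tuple[str, str]] = []
    for gwas in gwas_traits:
        for site in sentinel_sites:
            recs = scans[site]
            if not recs:
                untestable.append((site, gwas.trait))
                continue
            bonf = 0.05 / max(n_tested[site], 1)
            clumped = ld_clump([r for r in recs if r.p < bonf], g, clump_r2)
            usable = [r for r in clumped if r.snp in gwas.df.index]
            if not usable:
                untestable.append((site, gwas.trait))
                continue
            if len(usable) == 1:
                res = wald_ratio(usable[0], gwas.df.loc[usable[0].snp], trait=gwas.trait)
            else:
                res = ivw_mr(usable, gwas.df, trait=gwas.trait)
            # Steiger with instrument-strength r2 from the strongest instrument
            best = min(usable, key=lambda r: r.p)
            out_row = gwas.df.loc[best.snp]
            r2_out = outcome_r2(out_row["beta"], out_row["se"], int(out_row["n"]))
            direction, sp = steiger_test(best.r2, best.n, r2_out, int(out_row["n"]))
            res.steiger_direction = direction
            res.steiger_p = sp
            rows.append(res)
            # correlated-instrument sensitivity set
            sens = [r for r in ld_clump([r for r in recs if r.p < bonf], g, sensitivity_r2)
                    if r.snp in gwas.df.index]
            if len(sens) >= 3:
                for est in (ivw_mr(sens, gwas.df, trait=gwas.trait, effects="random"),
                            egger_mr(sens, gwas.df, trait=gwas.trait)):
                    est.method += "_sens"
                    rows.append(est)

    if untestable:
        logger.info("mr_pipeline: %d sentinel-trait pairs without usable instruments",
                    len(untestable))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if out.empty:
        out = pd.DataFrame(columns=[f.name for f in MRResult.__dataclass_fields__.values()]
                           + ["causal"])
        out.attrs["untestable"] = untestable
        return out
    primary = ~out["method"].str.endswith("_sens")
    out.loc[primary, "q"] = bh_fdr(out.loc[primary, "p"])
    out.loc[primary, "q_steiger"] = bh_fdr(out.loc[primary, "steiger_p"])
    out["causal"] = (
        primary
        & (out["q"] < q_threshold)
        & (out["q_steiger"] < q_threshold)
        & (out["steiger_direction"] == "exposure->outcome")
    )
    out.attrs["untestable"] = untestable
    return out


def proxy_lookup(snp: str, g: GenotypeMatrix, r2_min: float = 0.8,
                 window: int = CIS_WINDOW) -> dict | None:
    """Best LD proxy for a SNP absent from the target dataset: the
    in-window SNP with the largest dosage r2, if >= r2_min.  The aligned
    allele flips to the other allele when the dosage correlation is
    negative."""
    if snp not in g.snp_ids:
        raise KeyError(f"{snp} not genotyped in the reference panel")
    row = g.snps.loc[snp]
    x = g.dosages.loc[snp].to_numpy(dtype=float)
    cands = g.snp_ids[(g.snps["chrom"] == row["chrom"]) &
                      ((g.snps["start"] - row["start"]).abs() <= window) &
                      (g.snp_ids != snp)]
    best, best_r = None, 0.0
    for c in cands:
        yv = g.dosages.loc[c].to_numpy(dtype=float)
        if np.std(yv) == 0 or np.std(x) == 0:
            continue
        r = float(np.corrcoef(x, yv)[0, 1])
        if r * r > best_r * best_r:
            best, best_r = c, r
    if best is None or best_r**2 < r2_min:
        logger.info("proxy_lookup: no proxy with r2 >= %.2f for %s", r2_min, snp)
        return None
    aligned = g.snps.loc[best, "effect_allele"] if best_r > 0 else g.snps.loc[best, "other_allele"]
    return {"proxy": best, "r2": best_r**2, "r": best_r, "aligned_allele": aligned}
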