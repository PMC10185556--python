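"""Target-gene assignment and methylation-expression association.

Sentinels are linked to candidate effector genes hierarchically:

1. genic — the sentinel lies in an exon, 5'/3' UTR, or within 5 kb of a
   promoter: the overlapping genes are the targets;
2. functional — otherwise, if the sentinel falls inside a distal interval
   of an interaction map (capture Hi-C or enhancer catalogue), the
   connected genes are the targets;
3. tad — otherwise, every gene whose TSS shares a topologically
   associated domain with the sentinel is a candidate target.

TAD input is first flattened by removing intervals strictly nested
inside a larger domain (retaining the largest domains maximises
coverage).  Methylation-expression pairs are then tested in the combined
two-depot sample with a per-participant random intercept (shared fitter
in mixedlm), and target genes are checked for over-representation among
differentially expressed genes with an exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneModelSet, IntervalSet, InteractionMap, MethylationMatrix
from .ewas import bh_fdr
from .mixedlm import fit_random_intercept
from .sentinels import SentinelLocus, exact_binomial

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 5000


@dataclass
class TargetAssignment:
    sentinel: str
    gene: str
    tier: str       # genic | functional | tad
    evidence: str   # feature class, interaction source, or TAD id


def merge_tads(raw: IntervalSet) -> IntervalSet:
    """Remove every TAD strictly contained within another; keep partial
    overlaps and one copy of exact duplicates."""
    d = raw.df.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
    keep = np.ones(len(d), dtype=bool)
    for chrom, sub in d.groupby("chrom"):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in range(len(idx)):
            contained = (starts <= starts[i]) & (ends >= ends[i]) & \
                        ((starts < starts[i]) | (ends > ends[i]))
            if contained.any():
                keep[idx[i]] = False
    return IntervalSet(d[keep].reset_index(drop=True))


def assign_targets(sentinels: list[SentinelLocus], genes: GeneModelSet,
                   interactions: InteractionMap, tads: IntervalSet,
                   promoter_flank: int = PROMOTER_FLANK) -> list[TargetAssignment]:
    """Hierarchical sentinel-to-gene assignment (tiers are exclusive: a
    sentinel only receives TAD targets when tiers 1-2 produced none)."""
    from .enrichment import _feature_class

    out: list[TargetAssignment] = []
    chroms = {g.chrom for g in genes} | set(tads.df["chrom"]) | set(interactions.df["chrom"])
    for s in sentinels:
        if s.chrom not in chroms:
            logger.info("sentinel %s on chromosome %s absent from annotations", s.sentinel, s.chrom)
            continue
        genic = []
        for g in genes:
            if g.chrom != s.chrom:
                continue
            cls = _feature_class(g, s.start, promoter_flank)
            if cls in ("promoter", "utr5", "utr3", "exon"):
                genic.append(TargetAssignment(s.sentinel, g.gene_id, "genic", cls))
        if genic:
            out.extend(genic)
            continue
        hit = interactions.df[
            (interactions.df["chrom"] == s.chrom)
            & (interactions.df["start"] <= s.start)
            & (interactions.df["end"] > s.start)
        ]
        if len(hit):
            for _, row in hit.drop_duplicates(subset=["gene_id", "source"]).iterrows():
                out.append(TargetAssignment(s.sentinel, row["gene_id"], "functional", row["source"]))
            continue
        tad_hits = tads.overlapping(s.chrom, s.start, s.start + 1)
        found = set()
        for t_ix, t in tad_hits.iterrows():
            for g in genes:
                if g.chrom == s.chrom and t["start"] <= g.tss < t["end"] and g.gene_id not in found:
                    found.add(g.gene_id)
                    out.append(TargetAssignment(
                        s.sentinel, g.gene_id, "tad", f"{t['chrom']}:{t['start']}-{t['end']}"))
    return out


# ---------------------------------------------------------------------------
# methylation-expression association
# ---------------------------------------------------------------------------

def meth_expr_assoc(m: MethylationMatrix, e: ExpressionMatrix,
                    pairs: list[TargetAssignment],
                    covars: pd.DataFrame | None = None,
                    min_pairs: int = 10, q_threshold: float = 0.01) -> pd.DataFrame:
    """Random-intercept association of sentinel methylation with target
    gene logCPM in the combined two-depot sample.

    Samples are matched by column name between the methylation and
    expression matrices; the participant id from the sample sheet is the
    random-effect grouping.  Returns one row per (sentinel, gene) pair
    with slope (log2CPM per beta unit), se, p, BH q across tested pairs,
    variance components, and gate = q < q_threshold.
    """
    shared = [s for s in m.betas.columns if s in e.counts.columns]
    if not shared:
        raise ValueError("no shared samples between methylation and expression")
    logexpr = e.logcpm()[shared]
    betas = m.betas[shared]
    participants = m.sample_sheet.loc[shared, "participant"]
    if covars is not None:
        covars = covars.reindex(shared)

    rows = []
    for pair in pairs:
        if pair.sentinel not in betas.index or pair.gene not in logexpr.index:
            continue
        x = betas.loc[pair.sentinel].to_numpy(dtype=float)
        y = logexpr.loc[pair.gene].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if covars is not None:
            ok &= ~covars.isna().any(axis=1).to_numpy()
        if int(ok.sum()) < min_pairs:
            rows.append({"sentinel": pair.sentinel, "gene": pair.gene, "tier": pair.tier,
                         "slope": np.nan, "se": np.nan, "p": np.nan,
                         "sigma_u2": np.nan, "sigma_e2": np.nan,
                         "n": int(ok.sum()), "flag": "too_few_pairs"})
            continue
        X = pd.DataFrame({"intercept": 1.0, "meth": x[ok]})
        if covars is not None:
            X = pd.concat([X, covars.loc[np.array(shared)[ok]].reset_index(drop=True)], axis=1)
        fit = fit_random_intercept(y[ok], X, participants.to_numpy()[ok])
        rows.append({
            "sentinel": pair.sentinel, "gene": pair.gene, "tier": pair.tier,
            "slope": fit.params["meth"], "se": fit.bse["meth"], "p": fit.pvalues["meth"],
            "sigma_u2": fit.sigma_u2, "sigma_e2": fit.sigma_e2,
            "n": fit.nobs, "flag": "" if fit.method == "reml" else fit.method,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    tested = out["p"].notna()
    out["q"] = np.nan
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"])
    out["significant"] = out["q"] < q_threshold
    return out


# ---------------------------------------------------------------------------
# differential expression plumbing + enrichment
# ---------------------------------------------------------------------------

def differential_expression(e: ExpressionMatrix, pheno,
                            covars: pd.DataFrame | None = None) -> pd.DataFrame:
    """Naive per-gene OLS of logCPM on case/control status (+covariates).

    Plumbing for de_enrichment, not a negative-binomial model: returns
    per-gene log2 fold-ish effect, p and BH q.
    """
    samples = e.counts.columns
    y = e.logcpm()
    ph = pd.Series(pheno).reindex(samples) if isinstance(pheno, pd.Series) else pd.Series(np.asarray(pheno), index=samples)
    cols = {"intercept": np.ones(len(samples)), "pheno": ph.to_numpy(dtype=float)}
    if covars is not None:
        for c in covars.columns:
            cols[c] = covars.reindex(samples)[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    j = 1
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    Y = y.to_numpy(dtype=float)
    B = Y @ H.T
    resid = Y - B @ X.T
    df = len(samples) - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    from scipy import stats
    t = B[:, j] / se
    p = np.clip(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"effect": B[:, j], "se": se, "p": p, "q": bh_fdr(p)},
                        index=y.index)


def de_enrichment(target_genes: list[str], de_table: pd.DataFrame,
                  background_rate: float | None = None,
                  q_threshold: float = 0.01) -> dict:
    """Exact binomial test: are target genes differentially expressed more
    often than the background rate?

    ``de_table`` carries per-gene q-values for the whole universe; the
    background rate defaults to the universe DE fraction.
    """
    targets = [g for g in dict.fromkeys(target_genes) if g in de_table.index]
    n = len(targets)
    if n == 0:
        raise ValueError("no target genes present in the DE table")
    de = de_table["q"] < q_threshold
    if background_rate is None:
        background_rate = float(de.mean())
    k = int(de.loc[targets].sum())
    if background_rate >= 1.0:
        p = 1.0
    else:
        p = exact_binomial(k, n, background_rate, sided="one")
    return {"n_targets": n, "n_de": k, "observed_rate": k / n,
            "background_rate": background_rate, "p": p}
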