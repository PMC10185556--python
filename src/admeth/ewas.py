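"""Per-site case/control association, technical covariates, meta-analysis
and replication gating.

Each cohort is analysed separately: methylation beta at each CG site is
regressed on obesity status plus biological (age, sex, ethnicity) and
technical (control-probe principal component) covariates, so the obesity
coefficient is the adjusted case-minus-control difference in methylation
fraction.  Cohorts are combined by fixed-effect inverse-variance-weighted
(IVW) meta-analysis with Cochran's Q / I-squared heterogeneity, and
significant associations must pass a three-part gate: discovery FDR,
replication FDR with a consistent direction of effect, and epigenome-wide
significance (P < 1e-7) in the combined analysis.

Sites sharing a missingness pattern are solved in one batched
least-squares call; listwise deletion is applied per site.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .core_io import MethylationMatrix
from .sentinels import exact_binomial

logger = logging.getLogger(__name__)

EWS_P = 1e-7  # epigenome-wide significance for the combined analysis


# ---------------------------------------------------------------------------
# site filtering and normalisation
# ---------------------------------------------------------------------------

def filter_sites(m: MethylationMatrix, exclusions) -> MethylationMatrix:
    """Remove sites on an exclusion list (cross-hybridising probes, probes
    with SNPs in the probe sequence, ...)."""
    excl = set(exclusions)
    if not excl:
        warnings.warn("empty exclusion list; matrix passed through unchanged")
        return m
    present = excl & set(m.site_ids)
    absent = excl - present
    if absent:
        logger.info("%d exclusion ids not present in matrix", len(absent))
    keep = m.site_ids[~m.site_ids.isin(present)]
    logger.info("filter_sites: removed %d of %d sites", len(present), m.n_sites)
    return m.subset_sites(keep)


def drop_high_missing(m: MethylationMatrix, max_missing: float = 0.1) -> MethylationMatrix:
    """Drop sites with more than ``max_missing`` fraction missing betas."""
    frac = m.betas.isna().mean(axis=1)
    return m.subset_sites(m.site_ids[frac <= max_missing])


def quantile_normalize(m: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the cross-sample mean distribution of order
    statistics (limma-style normalizeQuantiles).

    Each sample's sorted values are replaced by the mean, across samples,
    of the values at the same rank; ties within a sample receive the mean
    of the reference values their ranks span.  Samples with missing values
    are mapped onto the reference distribution by quantile interpolation.
    """
    X = m.betas.to_numpy(dtype=float)
    n_sites, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalisation needs >=2 samples")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing sample")

    complete = ~np.isnan(X).any(axis=0)
    if complete.all():
        ref = np.sort(X, axis=0).mean(axis=1)
    else:
        # reference from complete samples if any, else interpolated marginals
        cols = X[:, complete] if complete.any() else X
        grid = (np.arange(n_sites) + 0.5) / n_sites
        parts = []
        for j in range(cols.shape[1]):
            v = np.sort(cols[:, j][~np.isnan(cols[:, j])])
            q = (np.arange(v.size) + 0.5) / v.size
            parts.append(np.interp(grid, q, v))
        ref = np.mean(parts, axis=0)

    out = np.empty_like(X)
    grid = (np.arange(n_sites) + 0.5) / n_sites
    for j in range(n_samp):
        col = X[:, j]
        ok = ~np.isnan(col)
        n_ok = int(ok.sum())
        if n_ok == n_sites:
            order = np.argsort(col, kind="mergesort")
            ranks = np.empty(n_sites)
            ranks[order] = np.arange(n_sites)
            normalized = ref[ranks.astype(int)]
            # ties: average the reference values the tied ranks span
            s = pd.Series(col)
            tied = s.duplicated(keep=False).to_numpy()
            if tied.any():
                df = pd.DataFrame({"v": col, "r": normalized})
                normalized = df.groupby("v")["r"].transform("mean").to_numpy()
            out[:, j] = normalized
        else:
            q = (stats.rankdata(col[ok], method="average") - 0.5) / n_ok
            out[ok, j] = np.interp(q, grid, ref)
            out[~ok, j] = np.nan
    betas = pd.DataFrame(out, index=m.betas.index, columns=m.betas.columns)
    return MethylationMatrix(betas.clip(0.0, 1.0), m.sites, m.sample_sheet)


def control_probe_pcs(controls: pd.DataFrame, var_target: float = 0.95,
                      max_pcs: int | None = None) -> pd.DataFrame:
    """Principal-component scores of control-probe intensities.

    ``controls`` is probes x samples (complete, no missing).  Returns the
    smallest number of PCs whose cumulative explained variance reaches
    ``var_target`` (the paper-style ">95% of control probe technical
    variation" rule), as a centred samples x PCs score matrix.
    """
    if controls.isna().any().any():
        raise ValueError("control probe matrix must be complete")
    if controls.shape[1] < 2:
        raise ValueError("need >=2 samples for control-probe PCA")
    X = controls.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    tot = var.sum()
    if tot == 0:
        raise ValueError("control probes have zero variance")
    cum = np.cumsum(var) / tot
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    if max_pcs is not None:
        k = min(k, max_pcs)
    scores = (Vt[:k].T * s[:k])  # samples x k, centred by construction
    return pd.DataFrame(scores, index=controls.columns,
                        columns=[f"cpPC{i+1}" for i in range(k)])


# ---------------------------------------------------------------------------
# association model
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _build_design(n: int, pheno: np.ndarray, covars: pd.DataFrame | None):
    cols = {"intercept": np.ones(n), "pheno": pheno.astype(float)}
    if covars is not None:
        for c in covars.columns:
            cols[str(c)] = covars[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the dependent columns by pivoted QR
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if abs(R[i, i]) <= tol]
        raise ValueError(f"perfect collinearity among design columns: {bad}")
    return X, names


def site_association(m: MethylationMatrix, pheno, covars: pd.DataFrame | None = None,
                     cohort: str = "cohort") -> pd.DataFrame:
    """Per-site OLS of methylation beta on a binary phenotype + covariates.

    Returns a DataFrame indexed by site id with columns effect (case minus
    control methylation fraction), se, p (two-sided t), q (BH within this
    cohort), n, direction and cohort.  Sites are deleted listwise for
    missing betas; a site is skipped (all-NaN row) when fewer than
    rank + 3 observations remain.
    """
    samples = m.betas.columns
    pheno = pd.Series(pheno, index=samples if np.ndim(pheno) == 1 and not isinstance(pheno, pd.Series) else None)
    if isinstance(pheno, pd.Series) and not pheno.index.equals(pd.Index(samples)):
        pheno = pheno.reindex(samples)
    ph = pheno.to_numpy(dtype=float)
    if not np.isin(ph[~np.isnan(ph)], [0.0, 1.0]).all():
        raise ValueError("phenotype must be binary 0/1")
    if covars is not None:
        covars = covars.reindex(samples)
    X_full, names = _build_design(len(samples), ph, covars)
    j = names.index("pheno")

    Y = m.betas.to_numpy(dtype=float)
    n_sites = Y.shape[0]
    eff = np.full(n_sites, np.nan)
    se = np.full(n_sites, np.nan)
    pval = np.full(n_sites, np.nan)
    nobs = np.zeros(n_sites, dtype=int)

    miss = np.isnan(Y)
    patterns = {}
    if miss.any():
        keys = [tuple(row) for row in miss]
        for i, key in enumerate(keys):
            patterns.setdefault(key, []).append(i)
    else:
        patterns[tuple([False] * Y.shape[1])] = list(range(n_sites))

    p_cols = X_full.shape[1]
    for key, rows in patterns.items():
        keep = ~np.array(key)
        n = int(keep.sum())
        if n - p_cols < 3:
            continue  # site skipped, stays NaN-flagged
        X = X_full[keep]
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        Yk = Y[np.ix_(rows, np.flatnonzero(keep))]
        B = Yk @ H.T                       # sites x p
        resid = Yk - B @ X.T
        df = n - p_cols
        sigma2 = (resid**2).sum(axis=1) / df
        se_j = np.sqrt(sigma2 * XtX_inv[j, j])
        t = np.where(se_j > 0, B[:, j] / np.where(se_j > 0, se_j, 1.0), np.nan)
        p = 2 * stats.t.sf(np.abs(t), df)
        eff[rows] = B[:, j]
        se[rows] = se_j
        pval[rows] = np.clip(p, np.finfo(float).tiny, 1.0)
        nobs[rows] = n

    out = pd.DataFrame(
        {"effect": eff, "se": se, "p": pval, "q": np.nan, "n": nobs,
         "direction": np.sign(eff), "cohort": cohort},
        index=m.betas.index,
    )
    tested = out["p"].notna()
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"])
    return out


def ivw_meta(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis of two cohorts.

    Sites present (with finite estimates) in only one cohort are excluded.
    Returns per-site combined effect/se/p, Cochran's Q, I-squared and the
    per-cohort inputs.
    """
    shared = a.index.intersection(b.index)
    a = a.loc[shared]
    b = b.loc[shared]
    ok = a["se"].notna() & b["se"].notna()
    n_dropped = int((~ok).sum()) + (len(a.index.symmetric_difference(b.index)))
    if n_dropped:
        logger.info("ivw_meta: %d sites not present/estimable in both cohorts", n_dropped)
    a, b = a[ok], b[ok]
    wa = 1.0 / a["se"] ** 2
    wb = 1.0 / b["se"] ** 2
    wsum = wa + wb
    eff = (wa * a["effect"] + wb * b["effect"]) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = eff / se
    p = 2 * stats.norm.sf(np.abs(z))
    Q = wa * (a["effect"] - eff) ** 2 + wb * (b["effect"] - eff) ** 2
    df = 1  # two cohorts
    i2 = np.maximum(0.0, (Q - df) / Q.replace(0, np.nan)).fillna(0.0)
    return pd.DataFrame(
        {"effect": eff, "se": se, "p": np.clip(p, np.finfo(float).tiny, 1.0),
         "Q": Q, "I2": i2,
         "effect_a": a["effect"], "se_a": a["se"],
         "effect_b": b["effect"], "se_b": b["se"]},
        index=a.index,
    )


def replication_gate(disc: pd.DataFrame, repl: pd.DataFrame, meta: pd.DataFrame,
                     q_disc: float = 0.01, q_repl: float = 0.01,
                     p_meta: float = EWS_P) -> dict:
    """Three-part significance gate with a direction sign test.

    A site passes when it is (i) discovery-significant (FDR < q_disc),
    (ii) replication-significant (FDR < q_repl) with the same direction of
    effect, and (iii) epigenome-wide significant in the combined analysis
    (p < p_meta).  Also returns (k, n): how many discovery-significant
    sites are direction-consistent in replication, for the sign test.
    """
    shared = disc.index.intersection(repl.index).intersection(meta.index)
    d, r, mt = disc.loc[shared], repl.loc[shared], meta.loc[shared]
    disc_sig = d["q"] < q_disc
    consistent = np.sign(d["effect"]) == np.sign(r["effect"])
    n = int(disc_sig.sum())
    k = int((disc_sig & consistent).sum())
    passing = disc_sig & consistent & (r["q"] < q_repl) & (mt["p"] < p_meta)
    return {
        "sites": list(shared[passing]),
        "n_consistent": k,
        "n_discovery_significant": n,
        "sign_test_p": exact_binomial(k, n, 0.5, "one") if n else float("nan"),
    }


def sensitivity_refit(m: MethylationMatrix, pheno, covars: pd.DataFrame | None,
                      extra: pd.DataFrame, cohort: str = "cohort") -> dict:
    """Re-fit the association model without and with extra covariates
    (cis-SNP dosages, contaminating-cell expression PCs, ...).

    Returns both result tables and the per-site effect attenuation
    1 - beta_with / beta_without.
    """
    base = site_association(m, pheno, covars, cohort=cohort)
    joint = covars.join(extra, how="inner") if covars is not None else extra
    adj = site_association(m, pheno, joint, cohort=cohort + "+extra")
    with np.errstate(divide="ignore", invalid="ignore"):
        atten = 1.0 - adj["effect"] / base["effect"]
    return {"without": base, "with": adj, "attenuation": atten}
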