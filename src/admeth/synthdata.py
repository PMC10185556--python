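"""Synthetic two-cohort, two-depot methylome study with planted truth.

The generator emulates the statistical structure of a case/control
adipocyte methylome study so that every downstream stage of the pipeline
has a recoverable ground truth:

* two cohorts (discovery, replication), each with paired subcutaneous
  and visceral samples from the same participants;
* per-site baseline betas drawn on a logistic-latent scale (bimodal,
  array-like marginals), with additive group effects, cis-mQTL dosage
  effects, per-batch technical shifts and Gaussian noise, clamped to
  [0, 1];
* planted differential sites with |shift| ~ Uniform(0.01, 0.18) and a
  75% hypomethylation bias, optionally depot-specific;
* cis-mQTL genotype effects with optional high-LD partner SNPs;
* SNP -> CpG -> phenotype causal chains (forward) and
  SNP -> phenotype -> CpG chains (reverse) for directionality testing;
* negative-binomial expression counts whose log-mean is linear in
  planted methylation and TF expression, with a per-participant random
  intercept, wiring the mediation triples TF -> CpG -> target.

The same seed reproduces every matrix byte-for-byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GeneModelSet,
    GenotypeMatrix,
    GWASSummary,
    IntervalSet,
    InteractionMap,
    MethylationMatrix,
)

CHROMS = ("chr1", "chr2", "chr3", "chr4")
SITE_SPACING = 10_000  # bp between consecutive array sites (no accidental clumping)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 5,000 array sites; 24
    participants per case/control arm per cohort, each contributing one
    subcutaneous and one visceral sample (so 48 + 48 samples per cohort);
    4% of sites planted differential with |shift| ~ U(0.01, 0.18), 75%
    hypomethylated in cases; mQTLs shifting methylation 0.05 per allele
    at MAF in [0.1, 0.4]; beta-scale noise sd 0.05.
    """

    seed: int
    n_sites: int = 5000
    n_genes: int = 300
    n_snps: int = 200
    n_per_group: int = 24              # participants per arm per cohort
    frac_differential: float = 0.04
    effect_low: float = 0.01
    effect_high: float = 0.18
    frac_hypo: float = 0.75            # planted effects negative in cases
    frac_shared_across_depots: float = 0.5
    noise_sd: float = 0.05
    batch_sd: float = 0.01
    n_batches: int = 2
    # mQTL architecture
    n_mqtl: int = 40
    mqtl_shift: float = 0.05           # beta units per allele
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_partner_flip: float = 0.05      # allele-flip prob for high-LD partner SNPs
    # causal chains
    n_chains_forward: int = 8
    n_chains_reverse: int = 4
    chain_snp_meth: float = 0.10       # forward: mean beta units per allele
    chain_snp_meth_jitter: float = 0.4  # per-chain strength ~ U(1-j, 1+j) x mean
    chain_meth_phen: float = 2.0       # forward: phenotype sd per beta unit
    reverse_outcome_beta: float = 1.2  # reverse: direct SNP -> phenotype effect
    reverse_snp_meth: float = 0.05     # reverse: induced SNP -> CpG effect
    gwas_n: int = 100_000
    # expression / mediation
    n_expr_links: int = 30
    expr_slope: float = -2.0           # log2CPM per beta unit
    expr_dispersion: float = 0.05
    participant_sd: float = 0.5        # random-intercept sd on log scale
    n_mediation: int = 5
    med_tf_meth: float = 0.04          # beta units per TF-expression sd
    med_meth_target: float = -2.0      # log2 units per beta unit
    med_direct: float = 0.3            # direct TF -> target, log2 per TF sd
    # annotations
    feature_fold: float = 3.0
    feature_rate: float = 0.10
    interaction_fraction: float = 0.5
    tad_nesting: int = 1

    def __post_init__(self):
        for frac in (self.frac_differential, self.frac_hypo,
                     self.frac_shared_across_depots, self.interaction_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    sites: pd.DataFrame       # per planted site: effect, depot
    mqtls: pd.DataFrame       # site, snp, beta (per allele), maf
    chains: pd.DataFrame      # snp, site, kind, b_snp_meth, b_meth_phen, b_out
    links: pd.DataFrame       # site, gene, slope (log2CPM per beta unit)
    mediation: pd.DataFrame   # tf_gene, site, target_gene, a, b, c
    snps: pd.DataFrame        # all SNPs: chrom, start, effect_allele, other_allele, maf

    def check_integrity(self, meth: MethylationMatrix, expr, geno: GenotypeMatrix):
        assert set(self.sites.index) <= set(meth.site_ids)
        assert set(self.mqtls["snp"]) <= set(geno.snp_ids)
        assert set(self.chains["snp"]) <= set(geno.snp_ids)
        if expr is not None:
            assert set(self.links["gene"]) <= set(expr.gene_ids)
            assert set(self.mediation["target_gene"]) <= set(expr.gene_ids)


@dataclass
class SimResult:
    cohorts: dict[str, MethylationMatrix]
    expression: "object"              # ExpressionMatrix
    genotypes: GenotypeMatrix
    truth: TruthTable
    controls: dict[str, pd.DataFrame] = field(default_factory=dict)
    tf_expression: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _site_layout(cfg: SimConfig, rng) -> pd.DataFrame:
    per_chrom = int(np.ceil(cfg.n_sites / len(CHROMS)))
    chroms, starts = [], []
    for c in CHROMS:
        k = min(per_chrom, cfg.n_sites - len(chroms))
        pos = SITE_SPACING * (1 + np.arange(k)) + rng.integers(0, 2000, size=k)
        chroms += [c] * k
        starts += list(pos)
        if len(chroms) >= cfg.n_sites:
            break
    ids = [f"cg{i:07d}" for i in range(cfg.n_sites)]
    return pd.DataFrame({"chrom": chroms, "start": starts}, index=pd.Index(ids, name="site"))


def _baseline_betas(cfg: SimConfig, rng) -> np.ndarray:
    comp = rng.choice(3, size=cfg.n_sites, p=[0.4, 0.4, 0.2])
    latent = np.where(comp == 0, rng.normal(-3, 1, cfg.n_sites),
                      np.where(comp == 1, rng.normal(3, 1, cfg.n_sites),
                               rng.normal(0, 1, cfg.n_sites)))
    return 1.0 / (1.0 + np.exp(-latent))


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate the full synthetic study; see the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    sites = _site_layout(cfg, rng)
    baseline = _baseline_betas(cfg, rng)

    # --- planted differential sites -------------------------------------
    # planted at intermediate-methylation sites (0.2-0.8), where most real
    # sentinels sit and where a shift up to 0.18 survives clamping
    n_diff = int(round(cfg.frac_differential * cfg.n_sites))
    intermediate = np.flatnonzero((baseline > 0.2) & (baseline < 0.8))
    if len(intermediate) < n_diff:
        raise ValueError("too few intermediate-methylation sites to plant effects")
    diff_ix = rng.choice(intermediate, size=n_diff, replace=False)
    mag = rng.uniform(cfg.effect_low, cfg.effect_high, size=n_diff)
    sign = np.where(rng.random(n_diff) < cfg.frac_hypo, -1.0, 1.0)
    effects = mag * sign
    shared = rng.random(n_diff) < cfg.frac_shared_across_depots
    depot_of = np.where(shared, "both", rng.choice(["subc", "visc"], size=n_diff))
    truth_sites = pd.DataFrame(
        {"effect": effects, "depot": depot_of},
        index=sites.index[diff_ix])

    # --- SNPs: mQTLs (with LD partners), chain SNPs, null SNPs ----------
    n_chain = cfg.n_chains_forward + cfg.n_chains_reverse
    if cfg.n_mqtl + n_chain > n_diff:
        raise ValueError("not enough planted sites to host mQTLs and chains")
    special = rng.choice(n_diff, size=cfg.n_mqtl + n_chain, replace=False)
    mqtl_site_ix = diff_ix[special[:cfg.n_mqtl]]
    chain_site_ix = diff_ix[special[cfg.n_mqtl:]]

    bases = np.array(list("ACGT"))
    snp_rows, snp_ids = [], []

    def _new_snp(name, chrom, start, maf):
        ea, oa = rng.choice(bases, size=2, replace=False)
        snp_ids.append(name)
        snp_rows.append({"chrom": chrom, "start": int(start),
                         "effect_allele": ea, "other_allele": oa, "maf": maf})

    maf_lo, maf_hi = cfg.maf_range
    for k, six in enumerate(mqtl_site_ix):
        row = sites.iloc[six]
        _new_snp(f"rs_mq{k:04d}", row["chrom"], row["start"] + rng.integers(-50_000, 50_000),
                 rng.uniform(maf_lo, maf_hi))
    for k, six in enumerate(chain_site_ix):
        row = sites.iloc[six]
        _new_snp(f"rs_ch{k:04d}", row["chrom"], row["start"] + rng.integers(-50_000, 50_000),
                 rng.uniform(maf_lo, maf_hi))
    n_named = len(snp_ids)
    n_null = max(cfg.n_snps - n_named, 0)
    for k in range(n_null):
        c = rng.choice(CHROMS)
        _new_snp(f"rs_nl{k:04d}", c, rng.integers(1, SITE_SPACING * cfg.n_sites // len(CHROMS)),
                 rng.uniform(maf_lo, maf_hi))
    snps = pd.DataFrame(snp_rows, index=pd.Index(snp_ids, name="snp"))

    mqtl_truth = pd.DataFrame({
        "site": sites.index[mqtl_site_ix],
        "snp": [f"rs_mq{k:04d}" for k in range(cfg.n_mqtl)],
        "beta": cfg.mqtl_shift,
        "maf": snps.loc[[f"rs_mq{k:04d}" for k in range(cfg.n_mqtl)], "maf"].to_numpy(),
    })
    kinds = ["forward"] * cfg.n_chains_forward + ["reverse"] * cfg.n_chains_reverse
    # per-chain instrument strengths are jittered so multi-instrument
    # estimators (IVW/Egger) see a spread of exposure effects
    jit = rng.uniform(1 - cfg.chain_snp_meth_jitter, 1 + cfg.chain_snp_meth_jitter,
                      size=n_chain)
    b1 = np.array([cfg.chain_snp_meth * jit[i] if k == "forward" else cfg.reverse_snp_meth
                   for i, k in enumerate(kinds)])
    chain_truth = pd.DataFrame({
        "snp": [f"rs_ch{k:04d}" for k in range(n_chain)],
        "site": sites.index[chain_site_ix],
        "kind": kinds,
        "b_snp_meth": b1,
        "b_meth_phen": [cfg.chain_meth_phen if k == "forward" else 0.0 for k in kinds],
        "b_out": [b1[i] * cfg.chain_meth_phen if k == "forward"
                  else cfg.reverse_outcome_beta for i, k in enumerate(kinds)],
    })

    # --- participants, genotypes ----------------------------------------
    cohorts = {}
    controls = {}
    all_samples: list[str] = []
    sample_meta = []
    participant_dosage = {}

    snp_effect_on_site = np.zeros((cfg.n_sites, len(snps)))
    for _, r in mqtl_truth.iterrows():
        snp_effect_on_site[sites.index.get_loc(r["site"]), snps.index.get_loc(r["snp"])] = r["beta"]
    for _, r in chain_truth.iterrows():
        snp_effect_on_site[sites.index.get_loc(r["site"]), snps.index.get_loc(r["snp"])] = r["b_snp_meth"]

    # beta-value variability shrinks toward the 0/1 boundaries on real
    # arrays; full noise_sd applies at intermediate methylation
    noise_scale = cfg.noise_sd * (0.25 + 0.75 * 4 * baseline * (1 - baseline))

    clamp_warn = 0
    total_draws = 0
    betas_by_cohort = {}
    for cohort in ("discovery", "replication"):
        pref = cohort[0].upper()
        parts = [f"{pref}{i:03d}" for i in range(2 * cfg.n_per_group)]
        case = np.repeat([1, 0], cfg.n_per_group)
        age = rng.normal(45, 10, len(parts))
        sex = rng.integers(0, 2, len(parts))
        eth = rng.integers(0, 3, len(parts))
        dos = rng.binomial(2, snps["maf"].to_numpy()[None, :], size=(len(parts), len(snps)))
        for p, d in zip(parts, dos):
            participant_dosage[p] = d.astype(float)

        cols, col_meta = [], []
        per_cohort_batches = rng.integers(0, cfg.n_batches, len(parts) * 2)
        batch_shift = rng.normal(0, cfg.batch_sd, size=(cfg.n_sites, cfg.n_batches))
        bi = 0
        beta_cols = {}
        for depot in ("subc", "visc"):
            for ix, p in enumerate(parts):
                samp = f"{p}_{depot}"
                b = baseline.copy()
                if case[ix]:
                    apply = (depot_of == "both") | (depot_of == depot)
                    b[diff_ix[apply]] += effects[apply]
                b += snp_effect_on_site @ participant_dosage[p]
                batch = int(per_cohort_batches[bi]); bi += 1
                b += batch_shift[:, batch]
                b += rng.normal(0, noise_scale, cfg.n_sites)
                clamp_warn += int(((b < 0) | (b > 1)).sum())
                total_draws += cfg.n_sites
                beta_cols[samp] = np.clip(b, 0.0, 1.0)
                col_meta.append({"sample": samp, "cohort": cohort, "depot": depot,
                                 "participant": p, "case": int(case[ix]),
                                 "age": age[ix], "sex": int(sex[ix]),
                                 "ethnicity": int(eth[ix]), "batch": batch})
        sheet = pd.DataFrame(col_meta).set_index("sample")
        betas = pd.DataFrame(beta_cols, index=sites.index)
        betas_by_cohort[cohort] = betas
        sample_meta.append(sheet)
        all_samples += list(betas.columns)
        # control-probe intensities: batch + a few technical factors
        # dominate, so a handful of PCs explain >95% of the variance
        factors = rng.normal(0, 1, size=(3, len(sheet)))
        loadings = rng.normal(0, 10, size=(20, 3))
        ctrl = rng.normal(1000, 2, size=(20, len(sheet)))
        ctrl += 50 * sheet["batch"].to_numpy()[None, :]
        ctrl += loadings @ factors
        controls[cohort] = pd.DataFrame(
            ctrl, index=[f"ctrl{i:02d}" for i in range(20)], columns=sheet.index)

    if total_draws and clamp_warn / total_draws > 0.01:
        warnings.warn(f"{clamp_warn} of {total_draws} beta draws "
                      f"({clamp_warn / total_draws:.1%}) clamped to [0,1]")

    sheet_all = pd.concat(sample_meta)
    for cohort in ("discovery", "replication"):
        cohorts[cohort] = MethylationMatrix(betas_by_cohort[cohort], sites.copy(), sheet_all)

    # LD partner SNPs for clumping tests: near-copies of mQTL SNPs
    partner_rows, partner_ids = [], []
    for k in range(cfg.n_mqtl):
        src = f"rs_mq{k:04d}"
        name = f"rs_ld{k:04d}"
        partner_ids.append(name)
        r = snps.loc[src]
        partner_rows.append({"chrom": r["chrom"], "start": r["start"] + 500,
                             "effect_allele": r["effect_allele"],
                             "other_allele": r["other_allele"], "maf": r["maf"]})
    if partner_rows:
        partners = pd.DataFrame(partner_rows, index=pd.Index(partner_ids, name="snp"))
        for p in participant_dosage:
            d = participant_dosage[p]
            extra = d[:cfg.n_mqtl].copy()
            flip = rng.random(cfg.n_mqtl) < cfg.ld_partner_flip
            resample = rng.binomial(2, partners["maf"].to_numpy())
            extra[flip] = resample[flip]
            participant_dosage[p] = np.concatenate([d, extra])
        snps = pd.concat([snps, partners])

    dosage_cols = {s: participant_dosage[s.rsplit("_", 1)[0]] for s in all_samples}
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosage_cols, index=snps.index),
        snps[["chrom", "start", "effect_allele", "other_allele"]].copy())

    # --- expression (replication cohort) --------------------------------
    from .core_io import ExpressionMatrix

    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    expr_sheet = sheet_all[sheet_all["cohort"] == "replication"]
    expr_samples = list(expr_sheet.index)
    meth_repl = betas_by_cohort["replication"]

    linkable = truth_sites.index[~truth_sites.index.isin(chain_truth["site"])]
    n_links = min(cfg.n_expr_links, len(linkable))
    link_sites = list(rng.choice(linkable, size=n_links, replace=False))
    link_genes = list(rng.choice(cfg.n_genes, size=n_links, replace=False))
    links = pd.DataFrame({"site": link_sites,
                          "gene": [gene_ids[i] for i in link_genes],
                          "slope": cfg.expr_slope})

    med_rows = []
    tf_latent = {}
    free_genes = [i for i in range(cfg.n_genes) if i not in set(link_genes)]
    med_pool = [s for s in truth_sites.index
                if s not in set(link_sites) and s not in set(chain_truth["site"])]
    n_med = min(cfg.n_mediation, len(med_pool), (len(free_genes) - 1) // 2)
    med_sites = list(rng.choice(med_pool, size=n_med, replace=False))
    for k in range(n_med):
        tf_g = gene_ids[free_genes[2 * k]]
        target_g = gene_ids[free_genes[2 * k + 1]]
        med_rows.append({"tf_gene": tf_g, "site": med_sites[k], "target_gene": target_g,
                         "a": cfg.med_tf_meth, "b": cfg.med_meth_target,
                         "c": cfg.med_direct})
        tf_latent[tf_g] = rng.normal(0, 1, len(expr_samples))
    mediation = pd.DataFrame(
        med_rows, columns=["tf_gene", "site", "target_gene", "a", "b", "c"])

    # TF expression feeds back into methylation at the mediated site
    for row in med_rows:
        z = tf_latent[row["tf_gene"]]
        six = sites.index.get_loc(row["site"])
        vals = meth_repl.loc[row["site"], expr_samples].to_numpy() + row["a"] * z
        meth_repl.loc[row["site"], expr_samples] = np.clip(vals, 0, 1)

    log_base = rng.normal(np.log(500), 1.0, cfg.n_genes)
    u_part = {p: rng.normal(0, cfg.participant_sd)
              for p in expr_sheet["participant"].unique()}
    ln2 = np.log(2.0)
    mu = np.exp(log_base)[:, None] * np.ones((1, len(expr_samples)))
    logmu = np.log(mu)
    for j, s in enumerate(expr_samples):
        logmu[:, j] += u_part[expr_sheet.loc[s, "participant"]]
    for _, r in links.iterrows():
        gix = gene_ids.index(r["gene"])
        meth = meth_repl.loc[r["site"], expr_samples].to_numpy(dtype=float)
        logmu[gix] += ln2 * r["slope"] * (meth - meth.mean())
    for row in med_rows:
        z = tf_latent[row["tf_gene"]]
        gix = gene_ids.index(row["tf_gene"])
        logmu[gix] += ln2 * 1.0 * z        # TF gene expresses its own latent
        tix = gene_ids.index(row["target_gene"])
        meth = meth_repl.loc[row["site"], expr_samples].to_numpy(dtype=float)
        logmu[tix] += ln2 * (row["c"] * z + row["b"] * (meth - meth.mean()))
    shape = 1.0 / cfg.expr_dispersion
    lam = rng.gamma(shape, np.exp(logmu) / shape)
    counts = rng.poisson(lam)
    expression = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=expr_samples),
        sample_sheet=sheet_all)

    truth = TruthTable(sites=truth_sites, mqtls=mqtl_truth, chains=chain_truth,
                       links=links, mediation=mediation, snps=snps)
    truth.check_integrity(cohorts["discovery"], expression, genotypes)
    tf_df = pd.DataFrame(tf_latent, index=expr_samples).T if tf_latent else None
    return SimResult(cohorts=cohorts, expression=expression, genotypes=genotypes,
                     truth=truth, controls=controls, tf_expression=tf_df)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig, truth: TruthTable,
                         sites: pd.DataFrame) -> dict:
    """Feature tracks, interactions, gene models and TADs consistent with
    the planted truth.

    ``sites`` is the site table (chrom, start) of the generated matrices.
    The "enhancer" feature covers planted differential sites at
    cfg.feature_fold times the background rate; interactions connect a
    fraction of planted intergenic sites to their true target genes; TADs
    tile each chromosome with cfg.tad_nesting levels of nested intervals
    so the hierarchical merge has work to do.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    planted = sites.index.isin(truth.sites.index)
    hit_rate = cfg.feature_fold * cfg.feature_rate
    if hit_rate > 1:
        raise ValueError(
            f"fold {cfg.feature_fold} unattainable at background rate "
            f"{cfg.feature_rate}; maximum achievable fold is {1 / cfg.feature_rate:.2f}")
    member = np.where(planted, rng.random(len(sites)) < hit_rate,
                      rng.random(len(sites)) < cfg.feature_rate)
    rows = [{"chrom": c, "start": max(0, s - 50), "end": s + 51, "label": "enhancer", "strand": "."}
            for c, s in zip(sites.loc[member, "chrom"], sites.loc[member, "start"])]
    enhancers = IntervalSet(pd.DataFrame(rows)) if rows else IntervalSet(
        pd.DataFrame(columns=["chrom", "start", "end", "label", "strand"]))

    # chromatin states: partition each chromosome into alternating labels
    state_rows = []
    labels = ["enh_state", "tss_state", "quies"]
    for c in CHROMS:
        sub = sites[sites["chrom"] == c]
        if sub.empty:
            continue
        end = int(sub["start"].max()) + SITE_SPACING
        width = 50_000
        for k, s in enumerate(range(0, end, width)):
            state_rows.append({"chrom": c, "start": s, "end": s + width,
                               "label": labels[k % len(labels)], "strand": "."})
    states = IntervalSet(pd.DataFrame(state_rows))

    # gene models: evenly spaced genes with promoter/UTR/exon structure
    genes = {}
    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    per_chrom = int(np.ceil(cfg.n_genes / len(CHROMS)))
    gix = 0
    chrom_span = SITE_SPACING * (cfg.n_sites // len(CHROMS) + 2)
    for c in CHROMS:
        for k in range(per_chrom):
            if gix >= cfg.n_genes:
                break
            tss = int((k + 1) * chrom_span / (per_chrom + 1))
            strand = "+" if (gix % 2 == 0) else "-"
            d = 1 if strand == "+" else -1
            exon1 = (tss, tss + 200) if d == 1 else (tss - 200, tss)
            exon2 = (tss + 1000 * d, tss + 1000 * d + 300) if d == 1 else (tss - 1300, tss - 1000)
            genes[gene_ids[gix]] = GeneModel(
                gene_id=gene_ids[gix], chrom=c, strand=strand, tss=tss,
                exons=sorted([exon1, exon2]),
                utr5=[exon1], utr3=[exon2])
            gix += 1
    gene_models = GeneModelSet(genes)

    # interactions: a fraction of intergenic planted sites -> their true target
    inter_rows = []
    for _, r in truth.links.iterrows():
        if rng.random() < cfg.interaction_fraction:
            srow = sites.loc[r["site"]]
            inter_rows.append({"chrom": srow["chrom"], "start": int(srow["start"]) - 500,
                               "end": int(srow["start"]) + 501, "gene_id": r["gene"],
                               "source": "capture_hic"})
    interactions = InteractionMap(pd.DataFrame(
        inter_rows, columns=["chrom", "start", "end", "gene_id", "source"]))

    # TADs: tiling domains plus nested children
    tad_rows = []
    for c in CHROMS:
        width = 400_000
        for s in range(0, chrom_span, width):
            tad_rows.append({"chrom": c, "start": s, "end": s + width,
                             "label": f"tad_{c}_{s // width}", "strand": "."})
            inner_s, inner_e = s, s + width
            for level in range(cfg.tad_nesting):
                q = (inner_e - inner_s) // 4
                inner_s, inner_e = inner_s + q, inner_e - q
                tad_rows.append({"chrom": c, "start": inner_s, "end": inner_e,
                                 "label": f"tad_{c}_{s // width}_n{level + 1}", "strand": "."})
    tads = IntervalSet(pd.DataFrame(tad_rows))

    return {"enhancers": enhancers, "states": states, "genes": gene_models,
            "interactions": interactions, "tads": tads}


# ---------------------------------------------------------------------------
# GWAS from planted chains
# ---------------------------------------------------------------------------

def simulate_gwas_from_chain(truth: TruthTable, n_gwas: int, seed: int,
                             pleiotropy: float = 0.0,
                             trait: str = "phenotype") -> GWASSummary:
    """Two-sample outcome GWAS implied by the planted causal chains.

    Forward-chain SNPs get beta_out ~ N(b_snp_meth * b_meth_phen + pleiotropy,
    se(n)); reverse-chain SNPs get their direct SNP->phenotype effect; every
    other SNP is pure noise.  se = 1/sqrt(2 maf (1-maf) n) on a unit-variance
    phenotype.
    """
    if n_gwas < 100:
        raise ValueError("n_gwas < 100 gives unstable standard errors")
    rng = np.random.default_rng(seed)
    from scipy import stats as _st

    snps = truth.snps
    maf = snps["maf"].to_numpy(dtype=float)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_gwas)
    true_beta = np.zeros(len(snps))
    chain = truth.chains.set_index("snp")
    for snp, row in chain.iterrows():
        ix = snps.index.get_loc(snp)
        true_beta[ix] = row["b_out"] + (pleiotropy if row["kind"] == "forward" else 0.0)
    beta = true_beta + rng.normal(0, se)
    p = np.clip(2 * _st.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "effect_allele": snps["effect_allele"].to_numpy(),
        "other_allele": snps["other_allele"].to_numpy(),
        "beta": beta, "se": se, "p": p, "n": n_gwas,
    }, index=snps.index)
    return GWASSummary(df, trait=trait)


def null_gwas(truth: TruthTable, n_gwas: int, seed: int,
              trait: str = "null") -> GWASSummary:
    """Outcome GWAS with no causal signal at any SNP (pure noise betas)."""
    empty = TruthTable(sites=truth.sites.iloc[:0], mqtls=truth.mqtls.iloc[:0],
                       chains=truth.chains.iloc[:0], links=truth.links.iloc[:0],
                       mediation=truth.mediation.iloc[:0], snps=truth.snps)
    return simulate_gwas_from_chain(empty, n_gwas, seed, trait=trait)


def site_stats(m: MethylationMatrix, depot: str | None = None) -> pd.DataFrame:
    """Per-site mean/sd pool statistics (for permutation matching) in one
    depot or across all samples."""
    betas = m.betas
    if depot is not None:
        keep = m.sample_sheet.loc[betas.columns, "depot"] == depot
        betas = betas.loc[:, keep.to_numpy()]
    return pd.DataFrame({
        "chrom": m.sites["chrom"], "start": m.sites["start"],
        "mean": betas.mean(axis=1), "sd": betas.std(axis=1, ddof=1),
    })
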