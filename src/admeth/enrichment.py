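"""Matched-permutation backgrounds and enrichment testing.

Methylation arrays interrogate a biased portion of the genome (CpG
islands, well-annotated genes), so enrichment of sentinel sites in a
genomic feature is always judged against matched permutation sets rather
than against the genome at large.  For every sentinel we pick 1000 array
sites with equivalent methylation level and variability using a sliding
tolerance ladder: rung r accepts candidates with |d mean| <= 0.025 r and
|d sd| <= 0.0025 r that lie more than 5 kb from the sentinel, and the
first rung yielding more than 1000 candidates is subsampled to exactly
1000 with a per-sentinel seeded stream.

Background replicate j is then the set formed by each sentinel's j-th
matched site, giving 1000 sentinel-list-sized replicates for empirical
p-values, alongside a Fisher exact test on pooled counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModelSet, GWASSummary, IntervalSet
from .sentinels import SentinelLocus

logger = logging.getLogger(__name__)

N_PERM = 1000
MEAN_STEP = 0.025
SD_STEP = 0.0025
MIN_DISTANCE = 5000
MAX_RUNG = 40

FEATURE_RANK = ["promoter", "utr5", "utr3", "exon", "intron", "intergenic"]


@dataclass
class PermutationSet:
    sentinel: str
    site_ids: list[str]       # exactly N_PERM unique matched sites
    rung: int                 # accepted ladder rung
    tol_mean: float
    tol_sd: float
    pool_size: int            # candidates available at acceptance


@dataclass
class EnrichmentResult:
    label: str
    observed: int
    expected: float           # mean background count
    fold: float               # observed / expected (inf flagged when expected 0)
    fisher_p: float
    empirical_p: float        # on the reported direction's side
    direction: str            # enriched | depleted
    empirical_p_enriched: float = float("nan")
    empirical_p_depleted: float = float("nan")


def build_permutation_set(sentinel: str, pool: pd.DataFrame, seed: int,
                          sentinel_index: int = 0, n_perm: int = N_PERM) -> PermutationSet:
    """Matched permutation set for one sentinel.

    ``pool`` is indexed by site id with columns chrom, start, mean, sd
    covering all array sites (the sentinel included).  The ladder widens
    until more than ``n_perm`` candidates qualify, then exactly
    ``n_perm`` are sampled without replacement using a stream seeded by
    (seed, sentinel_index) so regeneration is exact.
    """
    if sentinel not in pool.index:
        raise ValueError(f"sentinel {sentinel!r} absent from pool")
    srow = pool.loc[sentinel]
    same_chrom = pool["chrom"] == srow["chrom"]
    dist = np.where(same_chrom, (pool["start"] - srow["start"]).abs(), np.inf)
    eligible = (dist > MIN_DISTANCE) & (pool.index != sentinel)
    dmean = (pool["mean"] - srow["mean"]).abs().to_numpy()
    dsd = (pool["sd"] - srow["sd"]).abs().to_numpy()
    for rung in range(1, MAX_RUNG + 1):
        tol_m = MEAN_STEP * rung
        tol_s = SD_STEP * rung
        cand = eligible & (dmean <= tol_m) & (dsd <= tol_s)
        n_cand = int(cand.sum())
        if n_cand > n_perm:
            rng = np.random.default_rng([seed, sentinel_index])
            ids = pool.index[cand].to_numpy()
            chosen = rng.choice(ids, size=n_perm, replace=False)
            return PermutationSet(sentinel, list(chosen), rung, tol_m, tol_s, n_cand)
    raise ValueError(
        f"sentinel {sentinel!r}: only {int(eligible.sum())} eligible pool sites; "
        f"ladder exhausted at rung {MAX_RUNG} without >{n_perm} candidates")


def build_permutation_sets(sentinels: list[SentinelLocus], pool: pd.DataFrame,
                           seed: int, n_perm: int = N_PERM) -> list[PermutationSet]:
    return [build_permutation_set(s.sentinel, pool, seed, i, n_perm)
            for i, s in enumerate(sentinels)]


# ---------------------------------------------------------------------------
# enrichment machinery
# ---------------------------------------------------------------------------

def _enrich_from_flags(label: str, obs_flags: np.ndarray,
                       perm_flags: np.ndarray) -> EnrichmentResult:
    """Shared counting: obs_flags (n_sentinels,), perm_flags
    (n_sentinels, n_perm) booleans."""
    n_sent, n_perm = perm_flags.shape
    observed = int(obs_flags.sum())
    bg = perm_flags.sum(axis=0)          # count per background replicate
    expected = float(bg.mean())
    fold = observed / expected if expected > 0 else (np.inf if observed else 0.0)
    table = [[observed, n_sent - observed],
             [int(perm_flags.sum()), n_sent * n_perm - int(perm_flags.sum())]]
    fisher_p = stats.fisher_exact(table)[1]
    p_enr = (1 + int((bg >= observed).sum())) / (n_perm + 1)
    p_dep = (1 + int((bg <= observed).sum())) / (n_perm + 1)
    direction = "enriched" if observed > expected else "depleted"
    emp = p_enr if direction == "enriched" else p_dep
    return EnrichmentResult(label, observed, expected, fold, float(fisher_p),
                            emp, direction, p_enr, p_dep)


def feature_enrichment(sentinels: list[SentinelLocus], permsets: list[PermutationSet],
                       features: IntervalSet, pool: pd.DataFrame) -> list[EnrichmentResult]:
    """Observed vs matched-background overlap counts for every feature label.

    ``pool`` supplies coordinates (chrom, start) for the permutation site
    ids.  Permutation draw j across sentinels forms background replicate j.
    """
    if len(sentinels) != len(permsets):
        raise ValueError("one permutation set per sentinel required")
    sent_chrom = np.array([s.chrom for s in sentinels])
    sent_pos = np.array([s.start for s in sentinels])
    perm_ids = np.array([ps.site_ids for ps in permsets])      # n_sent x n_perm
    flat = perm_ids.ravel()
    pchrom = pool.loc[flat, "chrom"].to_numpy()
    ppos = pool.loc[flat, "start"].to_numpy()
    out = []
    for label in features.labels:
        obs = features.contains_points(sent_chrom, sent_pos, label)
        perm = features.contains_points(pchrom, ppos, label).reshape(perm_ids.shape)
        out.append(_enrich_from_flags(label, obs, perm))
    return out


def gwas_state_overlap(sentinels: list[SentinelLocus], gwas: GWASSummary,
                       snp_coords: pd.DataFrame, states: IntervalSet,
                       permsets: list[PermutationSet], pool: pd.DataFrame,
                       p_threshold: float = 5e-8,
                       semantics: str = "interval") -> EnrichmentResult:
    """Do sentinels share chromatin-state intervals with GWAS hits more
    often than matched background sites do?

    A site "overlaps GWAS" when the state interval containing it also
    contains a genome-wide-significant SNP (semantics='interval', the
    default) or, behind the flag semantics='label', when any significant
    SNP falls anywhere in the same state label.  ``snp_coords`` is indexed
    by snp id with columns chrom, start.
    """
    hits = gwas.significant(p_threshold)
    hit_coords = snp_coords.loc[snp_coords.index.intersection(hits.index)]
    n_outside = 0
    hit_intervals: set[int] = set()
    hit_labels: set[str] = set()
    for snp, row in hit_coords.iterrows():
        ix = states.containing_interval(str(row["chrom"]), int(row["start"]))
        if ix is None:
            n_outside += 1
            continue
        hit_intervals.add(ix)
        hit_labels.add(states.df.loc[ix, "label"])
    if n_outside:
        logger.info("gwas_state_overlap: %d significant SNPs outside any state", n_outside)

    def flag(chrom: str, pos: int) -> bool:
        ix = states.containing_interval(chrom, pos)
        if ix is None:
            return False
        if semantics == "interval":
            return ix in hit_intervals
        return states.df.loc[ix, "label"] in hit_labels

    obs = np.array([flag(s.chrom, s.start) for s in sentinels])
    perm = np.array([[flag(pool.loc[i, "chrom"], int(pool.loc[i, "start"]))
                      for i in ps.site_ids] for ps in permsets])
    return _enrich_from_flags("gwas_state_overlap", obs, perm)


# ---------------------------------------------------------------------------
# nearest gene and pathways
# ---------------------------------------------------------------------------

def _feature_class(gene, pos: int, promoter_flank: int = 5000) -> str | None:
    """Highest-priority feature class of ``gene`` overlapping pos, if any."""
    ps, pe = gene.promoter(promoter_flank)
    if ps <= pos < pe:
        return "promoter"
    for cls, ivs in (("utr5", gene.utr5), ("utr3", gene.utr3), ("exon", gene.exons)):
        if any(s <= pos < e for s, e in ivs):
            return cls
    gs, ge = gene.span()
    if gs <= pos < ge:
        return "intron"
    return None


def nearest_gene(chrom: str, pos: int, genes: GeneModelSet,
                 promoter_flank: int = 5000) -> tuple[str, str]:
    """Assign a site to a gene with promoter > 5'UTR/3'UTR > exon > intron
    > intergenic priority; ties and intergenic sites resolve to the
    nearest (then lowest-coordinate) TSS."""
    if len(genes) == 0:
        raise ValueError("empty gene set")
    candidates = []
    for g in genes:
        if g.chrom != chrom:
            continue
        cls = _feature_class(g, pos, promoter_flank)
        if cls is not None:
            candidates.append((FEATURE_RANK.index(cls), abs(g.tss - pos), g.tss, g.gene_id, cls))
    if candidates:
        candidates.sort()
        _, _, _, gid, cls = candidates[0]
        return gid, cls
    inter = [(abs(g.tss - pos), g.tss, g.gene_id) for g in genes if g.chrom == chrom]
    if not inter:
        inter = [(np.inf, g.tss, g.gene_id) for g in genes]
    inter.sort()
    return inter[0][2], "intergenic"


def pathway_enrichment(sentinel_genes: list[str], permset_genes: list[list[str]],
                       genesets: dict[str, set[str]],
                       universe: set[str] | None = None) -> list[EnrichmentResult]:
    """Gene-set enrichment of sentinel nearest genes against the matched
    permutation gene lists.

    Gene lists are deduplicated (one sentinel per gene, one permutation
    per gene) before counting.  ``permset_genes[j]`` is background
    replicate j's gene list.
    """
    obs_genes = list(dict.fromkeys(sentinel_genes))
    perm_unique = [set(g) for g in permset_genes]
    n_perm = len(perm_unique)
    out = []
    for name, members in genesets.items():
        if universe is not None:
            members = members & universe
        if not members:
            logger.info("pathway_enrichment: gene set %r empty in universe, skipped", name)
            continue
        observed = sum(g in members for g in obs_genes)
        bg = np.array([len(g & members) for g in perm_unique])
        expected = float(bg.mean())
        fold = observed / expected if expected > 0 else (np.inf if observed else 0.0)
        p_enr = (1 + int((bg >= observed).sum())) / (n_perm + 1)
        p_dep = (1 + int((bg <= observed).sum())) / (n_perm + 1)
        direction = "enriched" if observed > expected else "depleted"
        out.append(EnrichmentResult(name, observed, expected, fold, float("nan"),
                                    p_enr if direction == "enriched" else p_dep,
                                    direction, p_enr, p_dep))
    return out
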