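"""Readers, writers and domain containers for every external format the
pipeline touches.

All genomic coordinates are held internally as 0-based half-open
intervals.  CG sites are width-1 intervals anchored at the cytosine, so a
site printed at 1-based position ``p`` in a TSV is stored with
``start = p - 1``.  BED input is consumed natively (no shift); 1-based
TSV site/SNP positions are converted on read and restored on write.

Readers validate strictly and reject rather than repair: duplicated
identifiers, out-of-range values and malformed lines are hard errors that
name the offending file, line and field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input file violates a container invariant."""


def _err(path, msg, line=None, field_=None):
    loc = str(path)
    if line is not None:
        loc += f":{line}"
    if field_ is not None:
        loc += f" [{field_}]"
    raise ValidationError(f"{loc}: {msg}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

REQUIRED_SHEET_COLS = ("cohort", "depot", "participant", "case")


@dataclass
class MethylationMatrix:
    """Beta values (sites x samples) with site coordinates and sample sheet.

    ``betas`` is a DataFrame indexed by site id; ``sites`` holds one row per
    site with columns ``chrom`` and ``start`` (0-based position of the
    cytosine).  Missing betas are NaN, never silently dropped.
    """

    betas: pd.DataFrame
    sites: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self):
        if self.betas.index.has_duplicates:
            dups = self.betas.index[self.betas.index.duplicated()].unique()
            raise ValidationError(f"duplicated site ids: {list(dups[:5])}")
        vals = self.betas.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta out of [0,1] at site {self.betas.index[i]!r}, "
                f"sample {self.betas.columns[j]!r}: {vals[i, j]}"
            )
        if (self.sites["start"].to_numpy() < 0).any():
            raise ValidationError("site positions must be strictly positive (1-based)")
        missing = set(self.betas.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValidationError(f"samples absent from sample sheet: {sorted(missing)[:5]}")

    @property
    def site_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def n_sites(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def subset_sites(self, ids: Sequence[str]) -> "MethylationMatrix":
        ids = pd.Index(ids)
        return MethylationMatrix(self.betas.loc[ids], self.sites.loc[ids], self.sample_sheet)

    def subset_samples(self, samples: Sequence[str]) -> "MethylationMatrix":
        cols = [s for s in samples if s in self.betas.columns]
        return MethylationMatrix(self.betas[cols], self.sites, self.sample_sheet.loc[cols])


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative counts with derived log-scale values."""

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicated gene ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative expression counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def logcpm(self, prior: float = 0.5) -> pd.DataFrame:
        """log2 counts-per-million with a small prior count.

        logCPM = log2((count + prior) / (libsize + 2*prior) * 1e6), the
        standard voom-style transform without precision weights.
        """
        lib = self.counts.sum(axis=0).astype(float)
        return np.log2((self.counts + prior) / (lib + 2 * prior) * 1e6)


@dataclass
class GenotypeMatrix:
    """SNP x sample allele dosages in [0, 2]."""

    dosages: pd.DataFrame
    snps: pd.DataFrame  # chrom, start (0-based), effect_allele, other_allele

    def __post_init__(self):
        if self.dosages.index.has_duplicates:
            raise ValidationError("duplicated snp ids")
        vals = self.dosages.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 2))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"dosage out of [0,2] at snp {self.dosages.index[i]!r}, "
                f"sample {self.dosages.columns[j]!r}: {vals[i, j]}"
            )
        for col in ("effect_allele", "other_allele"):
            alleles = self.snps[col].astype(str).str.upper()
            if not alleles.isin(list("ACGT")).all():
                raise ValidationError(f"non-ACGT allele in column {col}")
            self.snps[col] = alleles

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def maf(self) -> pd.Series:
        freq = self.dosages.mean(axis=1) / 2.0
        return np.minimum(freq, 1 - freq)

    def is_palindromic(self) -> pd.Series:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ea = self.snps["effect_allele"]
        oa = self.snps["other_allele"]
        return pd.Series(
            [comp[a] == b for a, b in zip(ea, oa)], index=self.snp_ids, name="palindromic"
        )


@dataclass
class IntervalSet:
    """Genomic intervals (0-based half-open) with labels; sorted by (chrom, start)."""

    df: pd.DataFrame  # chrom, start, end, label, strand

    def __post_init__(self):
        d = self.df
        if (d["start"] >= d["end"]).any():
            row = d[d["start"] >= d["end"]].iloc[0]
            raise ValidationError(
                f"interval start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )
        if (d["label"].astype(str) == "").any():
            raise ValidationError("empty interval label")
        self.df = d.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """All intervals overlapping [start, end) on chrom."""
        d = self.df[self.df["chrom"] == chrom]
        hit = (d["start"] < end) & (d["end"] > start)
        return d[hit]

    def contains_points(self, chrom: np.ndarray, pos: np.ndarray, label: str | None = None) -> np.ndarray:
        """Vectorised point-membership: does any (optionally label-matched)
        interval contain each 0-based position?"""
        d = self.df if label is None else self.df[self.df["label"] == label]
        out = np.zeros(len(pos), dtype=bool)
        for c, sub in d.groupby("chrom", sort=False):
            m = np.asarray(chrom) == c
            if not m.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            # prefix-max of ends over the start-sorted list answers
            # "any interval with start <= p has end > p" in O(log n)
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], np.maximum.accumulate(ends[order])
            idx = np.searchsorted(starts, pos[m], side="right") - 1
            ok = idx >= 0
            ok[ok] = ends[idx[ok]] > pos[m][ok]
            out[m] = ok
        return out

    def containing_interval(self, chrom: str, pos: int) -> int | None:
        """Row index (into .df) of the first interval containing pos, else None."""
        d = self.df
        hit = (d["chrom"] == chrom) & (d["start"] <= pos) & (d["end"] > pos)
        idx = np.flatnonzero(hit.to_numpy())
        return int(idx[0]) if idx.size else None


@dataclass
class InteractionMap:
    """Distal interval -> target gene pairs (capture-HiC-like or
    enhancer-catalogue-like), deduplicated."""

    df: pd.DataFrame  # chrom, start, end, gene_id, source
    n_duplicates_dropped: int = 0

    def __post_init__(self):
        if (self.df["start"] >= self.df["end"]).any():
            raise ValidationError("interaction interval start >= end")
        before = len(self.df)
        self.df = self.df.drop_duplicates().reset_index(drop=True)
        self.n_duplicates_dropped += before - len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def genes_for_point(self, chrom: str, pos: int) -> list[str]:
        d = self.df
        hit = (d["chrom"] == chrom) & (d["start"] <= pos) & (d["end"] > pos)
        return sorted(d.loc[hit, "gene_id"].unique())


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def promoter(self, flank: int = 5000) -> tuple[int, int]:
        return (max(0, self.tss - flank), self.tss + flank + 1)

    def span(self) -> tuple[int, int]:
        pieces = self.exons + self.utr5 + self.utr3 + [(self.tss, self.tss + 1)]
        return (min(s for s, _ in pieces), max(e for _, e in pieces))


@dataclass
class GeneModelSet:
    genes: dict[str, GeneModel]

    def __post_init__(self):
        for g in self.genes.values():
            ex = sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if s2 < e1:
                    raise ValidationError(f"gene {g.gene_id}: overlapping exons")
            g.exons = ex

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]


@dataclass
class GWASSummary:
    """Per-SNP summary statistics for one trait."""

    df: pd.DataFrame  # index snp; effect_allele, other_allele, beta, se, p, n
    trait: str = "trait"

    def __post_init__(self):
        d = self.df
        if (d["se"] <= 0).any():
            bad = d.index[d["se"] <= 0][0]
            raise ValidationError(f"non-positive se at snp {bad!r}")
        if ((d["p"] <= 0) | (d["p"] > 1)).any():
            raise ValidationError("p outside (0,1]")
        for col in ("effect_allele", "other_allele"):
            alleles = d[col].astype(str).str.upper()
            if not alleles.isin(list("ACGT")).all():
                bad = d.index[~alleles.isin(list("ACGT"))][0]
                raise ValidationError(f"non-ACGT allele at snp {bad!r} in {col}")
            d[col] = alleles

    def significant(self, p_threshold: float = 5e-8) -> pd.DataFrame:
        return self.df[self.df["p"] < p_threshold]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "participant": str})
    if "sample" not in sheet.columns:
        _err(path, "sample sheet needs a 'sample' column")
    for col in REQUIRED_SHEET_COLS:
        if col not in sheet.columns:
            _err(path, f"sample sheet missing column {col!r}")
    return sheet.set_index("sample")


def read_matrix(path, kind: str, sample_sheet: pd.DataFrame | None = None):
    """Read a feature-by-sample TSV matrix.

    kind='methylation': columns site, chrom, pos (1-based), then samples.
    kind='expression':  columns gene, then samples.
    kind='genotype':    columns snp, chrom, pos (1-based), effect_allele,
                        other_allele, then samples.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if kind == "methylation":
        meta_cols = ["site", "chrom", "pos"]
    elif kind == "expression":
        meta_cols = ["gene"]
    elif kind == "genotype":
        meta_cols = ["snp", "chrom", "pos", "effect_allele", "other_allele"]
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    for col in meta_cols:
        if col not in df.columns:
            _err(path, f"missing column {col!r}")
    idcol = meta_cols[0]
    if df[idcol].duplicated().any():
        dup = df.loc[df[idcol].duplicated(), idcol].iloc[0]
        _err(path, f"duplicated id {dup!r}", field_=idcol)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    values = df[sample_cols].astype(float)
    values.index = df[idcol]

    if kind == "methylation":
        vals = values.to_numpy()
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            _err(path, f"beta {vals[i, j]} out of [0,1]",
                 line=i + 2, field_=f"site {values.index[i]!r} sample {sample_cols[j]!r}")
        if (df["pos"] <= 0).any():
            _err(path, "positions must be strictly positive 1-based integers")
        sites = pd.DataFrame(
            {"chrom": df["chrom"].astype(str).to_numpy(), "start": df["pos"].to_numpy() - 1},
            index=values.index,
        )
        if sample_sheet is None:
            sample_sheet = pd.DataFrame(
                {c: pd.NA for c in REQUIRED_SHEET_COLS}, index=pd.Index(sample_cols, name="sample")
            )
        return MethylationMatrix(values, sites, sample_sheet)
    if kind == "expression":
        return ExpressionMatrix(values, sample_sheet)
    snps = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            "start": df["pos"].to_numpy() - 1,
            "effect_allele": df["effect_allele"].astype(str).to_numpy(),
            "other_allele": df["other_allele"].astype(str).to_numpy(),
        },
        index=values.index,
    )
    return GenotypeMatrix(values, snps)


def write_matrix(obj, path) -> None:
    path = Path(path)
    if isinstance(obj, MethylationMatrix):
        out = obj.sites.copy()
        out.insert(0, "site", obj.site_ids)
        out["pos"] = out.pop("start") + 1
        out = pd.concat([out[["site", "chrom", "pos"]].reset_index(drop=True),
                         obj.betas.reset_index(drop=True)], axis=1)
    elif isinstance(obj, ExpressionMatrix):
        out = obj.counts.reset_index().rename(columns={obj.counts.index.name or "index": "gene"})
    elif isinstance(obj, GenotypeMatrix):
        out = obj.snps.copy()
        out.insert(0, "snp", obj.snp_ids)
        out["pos"] = out.pop("start") + 1
        out = pd.concat(
            [out[["snp", "chrom", "pos", "effect_allele", "other_allele"]].reset_index(drop=True),
             obj.dosages.reset_index(drop=True)], axis=1)
    else:
        raise TypeError(type(obj))
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_intervals(path, dialect: str = "bed") -> IntervalSet:
    """Read a BED3/BED4(+strand) file into an IntervalSet (no coordinate shift)."""
    if dialect != "bed":
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _err(path, f"malformed BED line ({len(parts)} fields)", line=ln)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _err(path, "non-integer coordinates", line=ln)
            if start >= end:
                _err(path, f"start {start} >= end {end}", line=ln)
            label = parts[3] if len(parts) > 3 and parts[3] else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            rows.append((parts[0], start, end, label, strand))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "strand"]))


def write_intervals(iv: IntervalSet, path) -> None:
    iv.df[["chrom", "start", "end", "label"]].to_csv(path, sep="\t", index=False, header=False)


def read_pairs(path, genes: GeneModelSet | None = None) -> InteractionMap:
    """Read a BEDPE-like TSV of distal interval -> gene interactions."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str, "source": str})
    for col in ("chrom", "start", "end", "gene_id", "source"):
        if col not in df.columns:
            _err(path, f"missing column {col!r}")
    imap = InteractionMap(df[["chrom", "start", "end", "gene_id", "source"]])
    if genes is not None:
        unknown = sorted(set(imap.df["gene_id"]) - set(genes.genes))
        if unknown:
            warnings.warn(f"{path}: {len(unknown)} interaction gene ids not in gene models "
                          f"(e.g. {unknown[:3]})")
    return imap


def write_pairs(imap: InteractionMap, path) -> None:
    imap.df.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> GeneModelSet:
    """Read a gene-model TSV: gene, chrom, strand, tss (1-based), and
    semicolon-separated 1-based inclusive interval lists exons/utr5/utr3
    ('start-end;start-end' or empty)."""

    def _parse(spec: str) -> list[tuple[int, int]]:
        if not isinstance(spec, str) or not spec:
            return []
        out = []
        for piece in spec.split(";"):
            s, e = piece.split("-")
            out.append((int(s) - 1, int(e)))  # 1-based inclusive -> 0-based half-open
        return out

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = {}
    for _, row in df.iterrows():
        genes[row["gene"]] = GeneModel(
            gene_id=row["gene"],
            chrom=row["chrom"],
            strand=row["strand"],
            tss=int(row["tss"]) - 1,
            exons=_parse(row.get("exons", "")),
            utr5=_parse(row.get("utr5", "")),
            utr3=_parse(row.get("utr3", "")),
        )
    return GeneModelSet(genes)


def write_gene_models(gms: GeneModelSet, path) -> None:
    def _fmt(ivs):
        return ";".join(f"{s + 1}-{e}" for s, e in ivs)

    rows = [
        {
            "gene": g.gene_id, "chrom": g.chrom, "strand": g.strand, "tss": g.tss + 1,
            "exons": _fmt(g.exons), "utr5": _fmt(g.utr5), "utr3": _fmt(g.utr3),
        }
        for g in gms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gwas_summary(path, trait: str | None = None) -> GWASSummary:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("snp", "effect_allele", "other_allele", "beta", "se", "p", "n"):
        if col not in df.columns:
            _err(path, f"missing column {col!r}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0].index[0]
        _err(path, "se <= 0", line=int(bad) + 2, field_="se")
    return GWASSummary(df.set_index("snp"), trait=trait or Path(str(path)).stem)


def write_gwas_summary(g: GWASSummary, path) -> None:
    g.df.reset_index().rename(columns={"index": "snp"}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                _err(path, "GMT line needs name, description and >=1 gene", line=ln)
            sets[parts[0]] = set(parts[2:]) - {""}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
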