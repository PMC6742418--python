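"""Tabular input/output: annotated variant tables, phenotype tables and
gene-level result reports.

The native variant format is a TSV with one row per variant: the
annotation columns (chrom, pos, ref, alt, gene, vclass, cadd, hgvs)
followed by a genotype column ``gt_<sample>`` and optionally a depth
column ``dp_<sample>`` per sample.  Genotypes are additive alt-allele
counts (0/1/2); ``.``, ``NA`` or an empty field mean missing.  Column
names are remappable through :class:`TableDialect`.  A VCF reader is
provided as an alternative genotype source; its annotations (gene,
class, CADD) must come from a sidecar table because consequence
annotation is upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    CohortData,
    ConsistencyError,
    RegionData,
    SchemaError,
    VariantRecord,
)

log = logging.getLogger(__name__)

MISSING_TOKENS = {".", "", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for the variant TSV."""

    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    gene: str = "gene"
    vclass: str = "vclass"
    cadd: str = "cadd"
    hgvs: str = "hgvs"
    gt_prefix: str = "gt_"
    dp_prefix: str = "dp_"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.chrom, self.pos, self.ref, self.alt, self.gene,
                self.vclass)


def _parse_geno(token) -> float:
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return np.nan
    try:
        g = float(s)
    except ValueError as exc:
        raise SchemaError(f"unparseable genotype {token!r}") from exc
    if g not in (0.0, 1.0, 2.0):
        raise SchemaError(f"genotype {token!r} not in {{0,1,2}} or missing")
    return g


def read_variant_table(path, dialect: TableDialect | None = None
                       ) -> tuple[list[str], list[RegionData]]:
    """Read a variant TSV into per-gene regions with a fixed variant order.

    Returns (sample_ids, regions).  Duplicate (chrom, pos, ref, alt) rows
    within a gene keep the first occurrence with a logged warning; variants
    are sorted ascending by (chrom, pos, ref, alt) regardless of row order.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in dialect.required:
        if col not in df.columns:
            raise SchemaError(f"variant table is missing column {col!r}")
    gt_cols = [c for c in df.columns if c.startswith(dialect.gt_prefix)]
    if not gt_cols:
        raise SchemaError(
            f"no genotype columns with prefix {dialect.gt_prefix!r}"
        )
    sample_ids = [c[len(dialect.gt_prefix):] for c in gt_cols]
    dp_cols = {
        s: dialect.dp_prefix + s
        for s in sample_ids
        if dialect.dp_prefix + s in df.columns
    }
    have_depth = len(dp_cols) == len(sample_ids)

    regions: list[RegionData] = []
    for gene, sub in df.groupby(dialect.gene, sort=True):
        dup = sub.duplicated(
            subset=[dialect.chrom, dialect.pos, dialect.ref, dialect.alt]
        )
        if dup.any():
            log.warning("%d duplicated variant rows in %s; keeping first",
                        int(dup.sum()), gene)
            sub = sub[~dup]
        records, g_rows, d_rows = [], [], []
        for row in sub.itertuples(index=False):
            rowd = dict(zip(sub.columns, row))
            cadd_s = str(rowd.get(dialect.cadd, "")).strip()
            records.append(
                VariantRecord(
                    chrom=str(rowd[dialect.chrom]),
                    pos=int(rowd[dialect.pos]),
                    ref=str(rowd[dialect.ref]),
                    alt=str(rowd[dialect.alt]),
                    gene=str(gene),
                    vclass=str(rowd[dialect.vclass]),
                    cadd=None if cadd_s in MISSING_TOKENS else float(cadd_s),
                    hgvs=(str(rowd[dialect.hgvs]).strip() or None)
                    if dialect.hgvs in sub.columns else None,
                )
            )
            g_rows.append([
                _parse_geno(rowd[dialect.gt_prefix + s]) for s in sample_ids
            ])
            if have_depth:
                d_rows.append([int(float(rowd[dp_cols[s]])) for s in sample_ids])
        order = sorted(range(len(records)), key=lambda i: records[i].key)
        G = np.array(g_rows, dtype=float)[order].T
        D = np.array(d_rows, dtype=int)[order].T if have_depth else None
        regions.append(
            RegionData(gene=str(gene),
                       variants=[records[i] for i in order], G=G, D=D)
        )
    return sample_ids, regions


def write_variant_table(sample_ids: list[str], regions: Iterable[RegionData],
                        path, dialect: TableDialect | None = None) -> None:
    """Serialize regions back to the variant TSV dialect (round-trippable)."""
    dialect = dialect or TableDialect()
    rows = []
    for region in regions:
        for j, v in enumerate(region.variants):
            row = {
                dialect.chrom: v.chrom, dialect.pos: v.pos,
                dialect.ref: v.ref, dialect.alt: v.alt,
                dialect.gene: v.gene, dialect.vclass: v.vclass,
                dialect.cadd: "" if v.cadd is None else repr(float(v.cadd)),
                dialect.hgvs: v.hgvs or "",
            }
            for i, s in enumerate(sample_ids):
                g = region.G[i, j]
                row[dialect.gt_prefix + s] = "." if np.isnan(g) else str(int(g))
                if region.D is not None:
                    row[dialect.dp_prefix + s] = str(int(region.D[i, j]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> CohortData:
    """Read a phenotype TSV with columns sample_id, status [, covariates...].

    ``status`` accepts case/control or 1/0; any further numeric columns
    become covariates after the synthesized intercept.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise SchemaError(f"phenotype table is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConsistencyError(f"duplicate sample ids: {dups[:5]}")
    mapping = {"case": 1.0, "control": 0.0, "1": 1.0, "0": 0.0}
    y = []
    for tok in df["status"]:
        key = str(tok).strip().lower()
        if key not in mapping:
            raise SchemaError(f"unknown status token {tok!r}")
        y.append(mapping[key])
    covar_cols = [c for c in df.columns if c not in ("sample_id", "status")]
    n = len(df)
    X = np.ones((n, 1 + len(covar_cols)))
    for k, c in enumerate(covar_cols):
        X[:, k + 1] = pd.to_numeric(df[c]).to_numpy()
    return CohortData(sample_ids=df["sample_id"].astype(str).tolist(),
                      y=np.array(y), X=X)


def load_study(variant_path, phenotype_path,
               dialect: TableDialect | None = None
               ) -> tuple[CohortData, list[RegionData]]:
    """Read variant + phenotype tables and align them on sample id."""
    sample_ids, regions = read_variant_table(variant_path, dialect)
    pheno = read_phenotype_table(phenotype_path)
    if set(sample_ids) != set(pheno.sample_ids):
        raise ConsistencyError(
            "variant and phenotype tables carry different sample sets"
        )
    order = [pheno.sample_ids.index(s) for s in sample_ids]
    cohort = CohortData(
        sample_ids=sample_ids,
        y=pheno.y[order],
        X=pheno.X[order],
    )
    return cohort, regions


def write_gene_results(results: pd.DataFrame, path) -> None:
    """Write a gene-level results table sorted by ascending p.

    Floats are serialized with 12 significant digits so a read-back
    reproduces the values; column order is preserved deterministically.
    """
    if "p" in results.columns and len(results):
        results = results.sort_values("p", kind="mergesort")
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gene_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_vcf(path, annotations: pd.DataFrame,
             samples: Optional[list[str]] = None
             ) -> tuple[list[str], list[RegionData]]:
    """Read genotypes from a VCF and join per-variant annotations.

    ``annotations`` must carry chrom, pos, ref, alt, gene, vclass and
    optionally cadd; variants absent from it are skipped.  Multi-allelic
    sites are decomposed to one record per alt allele, with the genotype
    counting that allele only.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), samples=samples)
    sample_ids = list(vcf.samples)
    ann = annotations.set_index(
        ["chrom", "pos", "ref", "alt"]
    ).sort_index()
    per_gene: dict[str, list] = {}
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            key = (str(rec.CHROM), int(rec.POS), rec.REF, alt)
            if key not in ann.index:
                continue
            meta = ann.loc[key]
            if isinstance(meta, pd.DataFrame):
                meta = meta.iloc[0]
            counts = np.full(len(sample_ids), np.nan)
            for si, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    continue
                counts[si] = sum(a == ai + 1 for a in alleles)
            cadd = meta.get("cadd", np.nan)
            record = VariantRecord(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                gene=str(meta["gene"]), vclass=str(meta["vclass"]),
                cadd=None if pd.isna(cadd) else float(cadd),
            )
            per_gene.setdefault(record.gene, []).append((record, counts))
    regions = []
    for gene in sorted(per_gene):
        items = sorted(per_gene[gene], key=lambda it: it[0].key)
        regions.append(
            RegionData(
                gene=gene,
                variants=[r for r, _ in items],
                G=np.column_stack([c for _, c in items]),
            )
        )
    return sample_ids, regions
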