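"""Variant/gene filtering and PCA-based ancestry-outlier exclusion.

The discovery-stage filters keep exonic/splicing variants that are rare in
controls (folded MAF at or below a ceiling, 1% by default), adequately
covered (read depth >= 10 in at least one sample), and drop genes left
with fewer than 10 variants, the minimum the region test requires.
Ancestry outliers are samples whose distance from their nearest population
centroid on the first two genotype principal components exceeds a
standard-deviation threshold (10 SD by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .types import CohortData, RegionData


class UndefinedFrequencyError(ValueError):
    """All genotypes missing in the requested subset."""


class InsufficientDataError(ValueError):
    """Too few common variants or samples for the PCA."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the variant, gene and ancestry filters."""

    maf_max: float = 0.01
    depth_min: int = 10
    depth_min_samples: int = 1
    exclude_classes: frozenset = frozenset({"synonymous", "other"})
    min_variants_per_gene: int = 10
    common_maf_min: float = 0.05
    outlier_sd: float = 10.0
    outlier_rule: str = "per_axis"  # "per_axis" | "euclidean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_max <= 0.5):
            raise ValueError("maf_max must lie in [0, 0.5]")
        if self.min_variants_per_gene < 1:
            raise ValueError("min_variants_per_gene must be >= 1")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


def compute_maf(genotypes: np.ndarray, subset: Optional[np.ndarray] = None) -> float:
    """Folded minor-allele frequency of one variant over a sample subset.

    Missing genotypes (NaN) are dropped from both numerator and
    denominator; the alt-allele frequency is folded to ``min(f, 1-f)``.
    """
    g = np.asarray(genotypes, dtype=float)
    if subset is not None:
        g = g[np.asarray(subset, dtype=bool)]
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise UndefinedFrequencyError("no non-missing genotypes in subset")
    f = g.sum() / (2.0 * g.size)
    return float(min(f, 1.0 - f))


@dataclass
class FilterReport:
    """Per-rule removal counts from the variant filter."""

    removed_class: int = 0
    removed_maf: int = 0
    removed_depth: int = 0
    kept: int = 0
    per_gene: dict = field(default_factory=dict)

    @property
    def removed_total(self) -> int:
        return self.removed_class + self.removed_maf + self.removed_depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["class", "control_maf", "depth", "kept"],
                "count": [self.removed_class, self.removed_maf,
                          self.removed_depth, self.kept],
            }
        )


def apply_variant_filters(regions: list[RegionData], cohort: CohortData,
                          cfg: FilterConfig | None = None
                          ) -> tuple[list[RegionData], FilterReport]:
    """Apply the variant-level filters to every region.

    A variant is retained iff its consequence class is not excluded, its
    folded MAF in controls is <= ``maf_max`` (boundary retained), and its
    read depth reaches ``depth_min`` in at least ``depth_min_samples``
    samples (regions without depth data pass the depth rule).  A variant
    failing several rules is counted once, under the first failing rule in
    the order class -> MAF -> depth.  Empty regions are kept in the output
    (the gene filter removes them).
    """
    cfg = cfg or FilterConfig()
    controls = cohort.control_mask()
    if not controls.any():
        raise ValueError("control subset is empty")
    report = FilterReport()
    out: list[RegionData] = []
    for region in regions:
        keep: list[int] = []
        for j, v in enumerate(region.variants):
            if v.vclass in cfg.exclude_classes:
                report.removed_class += 1
                continue
            try:
                maf = compute_maf(region.G[:, j], controls)
            except UndefinedFrequencyError:
                maf = 0.0
            if maf > cfg.maf_max:
                report.removed_maf += 1
                continue
            if region.D is not None:
                n_deep = int((region.D[:, j] >= cfg.depth_min).sum())
                if n_deep < cfg.depth_min_samples:
                    report.removed_depth += 1
                    continue
            keep.append(j)
        report.kept += len(keep)
        report.per_gene[region.gene] = len(keep)
        out.append(region.subset(keep))
    return out, report


def apply_gene_filter(regions: list[RegionData],
                      cfg: FilterConfig | None = None) -> list[RegionData]:
    """Drop genes with fewer than ``min_variants_per_gene`` variants."""
    cfg = cfg or FilterConfig()
    return [r for r in regions if r.n_variants >= cfg.min_variants_per_gene]


@dataclass
class AncestryResult:
    """Outlier flags and PC coordinates from the ancestry screen."""

    flags: np.ndarray
    pcs: np.ndarray
    clusters: np.ndarray
    centroids: np.ndarray

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "PC1": self.pcs[:, 0],
                "PC2": self.pcs[:, 1],
                "cluster": self.clusters,
                "flagged": self.flags,
            }
        )


def detect_ancestry_outliers(G_common: np.ndarray,
                             labels: Optional[list[str]] = None,
                             cfg: FilterConfig | None = None,
                             n_clusters: Optional[int] = None,
                             seed: int = 0) -> AncestryResult:
    """Flag samples far from any population centroid on the first two PCs.

    Genotypes are restricted to variants with folded MAF >=
    ``common_maf_min``, mean-imputed, standardized per variant, and
    projected onto two principal components.  Population clusters come
    from ``labels`` when given, otherwise from k-means on the PCs
    (``n_clusters`` populations, default 1).  Each sample's distance to
    its nearest centroid is measured in per-cluster, per-axis SD units;
    location and scale are estimated robustly (median and 1.4826*MAD) so
    that a handful of gross outliers inside a cluster cannot inflate its
    SD and mask themselves.  A sample is flagged when either axis
    (default rule) or the Euclidean SD-normalized distance exceeds
    ``outlier_sd``.
    """
    cfg = cfg or FilterConfig()
    G = np.asarray(G_common, dtype=float)
    if G.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for PCA")
    common = []
    for j in range(G.shape[1]):
        try:
            if compute_maf(G[:, j]) >= cfg.common_maf_min:
                common.append(j)
        except UndefinedFrequencyError:
            continue
    if len(common) < 2:
        raise InsufficientDataError(
            f"only {len(common)} variants with MAF >= {cfg.common_maf_min}"
        )
    X = G[:, common]
    col_mean = np.nanmean(X, axis=0)
    ii = np.where(np.isnan(X))
    X[ii] = col_mean[ii[1]]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    pcs = PCA(n_components=2, random_state=seed).fit_transform(X)

    if labels is not None:
        uniq = sorted(set(labels))
        clusters = np.array([uniq.index(l) for l in labels])
    else:
        k = n_clusters or 1
        clusters = KMeans(n_clusters=k, n_init=10,
                          random_state=seed).fit_predict(pcs)

    n = pcs.shape[0]
    ids = np.unique(clusters)
    centroids, scales = [], []
    for c in ids:
        member_pcs = pcs[clusters == c]
        mu = np.median(member_pcs, axis=0)
        s = 1.4826 * np.median(np.abs(member_pcs - mu), axis=0)
        s[s == 0] = np.finfo(float).tiny
        centroids.append(mu)
        scales.append(s)
    centroids = np.vstack(centroids)
    scales = np.vstack(scales)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        z = np.abs(pcs[i] - centroids) / scales  # clusters x 2
        dist = (
            z.max(axis=1)
            if cfg.outlier_rule == "per_axis"
            else np.sqrt((z ** 2).sum(axis=1))
        )
        flags[i] = dist.min() > cfg.outlier_sd
    return AncestryResult(flags=flags, pcs=pcs, clusters=clusters,
                          centroids=centroids)
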