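"""Core data containers for the case-control rare-variant analysis.

The pipeline works on three in-memory objects: :class:`VariantRecord`
(one annotated variant), :class:`CohortData` (phenotype + covariates for a
sample set) and :class:`RegionData` (the per-gene genotype/annotation
bundle that the region test consumes).  Genotypes are additive alt-allele
counts in {0, 1, 2}; missing calls are ``NaN`` and are never silently
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Closed vocabulary of functional consequence classes.
VCLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "nonframeshift_indel",
        "splicing",
        "synonymous",
        "other",
    }
)

#: Classes treated as protein-truncating/splice-disrupting in reports.
PTV_CLASSES = frozenset({"nonsense", "frameshift", "splicing"})


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ConsistencyError(ValueError):
    """Rows of an input table disagree with each other (samples, duplicates)."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant at a 1-based genomic position.

    ``cadd`` is the PHRED-scaled CADD deleteriousness score; ``None`` means
    the score is unavailable for this variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vclass: str
    cadd: Optional[float] = None
    hgvs: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vclass not in VCLASSES:
            raise ValueError(
                f"unknown variant class {self.vclass!r}; expected one of "
                f"{sorted(VCLASSES)}"
            )
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"CADD score must be >= 0, got {self.cadd}")

    @property
    def key(self) -> tuple:
        """Sort/identity key: (chrom, pos, ref, alt)."""
        return (_chrom_rank(self.chrom), self.pos, self.ref, self.alt)


def _chrom_rank(chrom: str) -> tuple:
    """Orderable key for chromosome labels (1..22 < X < Y < MT < others)."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (0, special[c], "")
    return (1, 0, c)


@dataclass
class CohortData:
    """Phenotype and covariate data for an ordered sample set.

    ``y`` is coded 1 = case, 0 = control.  ``X`` always carries an all-ones
    intercept as its first column.
    """

    sample_ids: list[str]
    y: np.ndarray
    X: np.ndarray
    ancestry_label: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        n = len(self.sample_ids)
        if self.y.shape != (n,):
            raise ConsistencyError(
                f"phenotype length {self.y.shape} != {n} samples"
            )
        if self.X.shape[0] != n:
            raise ConsistencyError(
                f"covariate rows {self.X.shape[0]} != {n} samples"
            )
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("phenotype vector must contain only 0/1")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def control_mask(self) -> np.ndarray:
        return self.y == 0


@dataclass
class RegionData:
    """Genotype, depth and annotation data for one gene region.

    ``G`` (samples x variants) holds additive alt-allele dosages with NaN
    for missing calls; ``D`` the matching read depths.  ``variants`` is
    strictly ordered by (chrom, pos, ref, alt) and this ordering defines
    the column order of ``G``/``D`` and the window indices used downstream.
    ``causal`` records planted truth (variant index -> log odds ratio) for
    simulated regions; it is empty for real data.
    """

    gene: str
    variants: list[VariantRecord]
    G: np.ndarray
    D: Optional[np.ndarray] = None
    causal: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        m = len(self.variants)
        if self.G.ndim != 2 or self.G.shape[1] != m:
            raise ConsistencyError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{m} variants"
            )
        if self.D is not None:
            self.D = np.asarray(self.D)
            if self.D.shape != self.G.shape:
                raise ConsistencyError("depth matrix shape != genotype shape")
        keys = [v.key for v in self.variants]
        if any(keys[i] >= keys[i + 1] for i in range(m - 1)):
            raise ValueError(
                f"variants of {self.gene} are not strictly ascending by "
                "(chrom, pos, ref, alt)"
            )
        vals = self.G[~np.isnan(self.G)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotypes must be in {0, 1, 2} or missing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    def subset(self, indices: Sequence[int]) -> "RegionData":
        """Region restricted to the given variant indices (0-based, kept in order)."""
        idx = sorted(indices)
        return RegionData(
            gene=self.gene,
            variants=[self.variants[i] for i in idx],
            G=self.G[:, idx],
            D=None if self.D is None else self.D[:, idx],
            causal={
                idx.index(i): lor for i, lor in self.causal.items() if i in idx
            },
        )

    def drop(self, indices: Sequence[int]) -> "RegionData":
        """Region with the given variant indices removed."""
        keep = [i for i in range(self.n_variants) if i not in set(indices)]
        return self.subset(keep)
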