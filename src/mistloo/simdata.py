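"""Synthetic case-control cohorts with planted rare-variant architecture.

The generator emulates the statistical structure a region-based
case-control analysis assumes: per-gene rare-variant genotype matrices
drawn under Hardy-Weinberg from a log-uniform minor-allele-frequency
spectrum, a logistic disease model with a planted causal subset, CADD-like
deleteriousness scores and consequence classes correlated with causality,
negative-binomial read depths, and (separately) multi-cluster common
variants for ancestry PCA.

Case-control ascertainment is by rejection sampling from the population
model: individuals are drawn until the requested case and control quotas
fill.  Because non-causal genes are independent of phenotype, only causal
genes are simulated during ascertainment; the rest are drawn afterwards
for the retained samples, which is distributionally exact and much faster.
All output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .stats import ContingencyTable
from .types import CohortData, RegionData, VariantRecord


class AscertainmentError(RuntimeError):
    """Requested case quota unreachable under the disease model."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the cohort simulator.

    Defaults mirror a two-series discovery design of roughly 400 cases and
    1000 controls screened over a candidate-gene panel, with rare variants
    (MAF between 1e-4 and 1%), causal effects of odds ratio 5 on a ~1%
    baseline-prevalence trait, and a 2:1 benign:damaging CADD separation.
    """

    n_cases: int = 398
    n_controls: int = 987
    n_genes: int = 20
    variants_min: int = 10
    variants_max: int = 40
    maf_min: float = 1e-4
    maf_max: float = 0.01
    causal_genes: int = 1
    causal_fraction: float = 0.25
    causal_logOR: float = float(np.log(5.0))
    baseline_logit: float = -4.6  # prevalence ~ 1%
    cadd_benign: tuple[float, float] = (0.0, 15.0)
    cadd_causal: tuple[float, float] = (15.0, 40.0)
    type_probs: dict = field(
        default_factory=lambda: {
            "missense": 0.80,
            "nonframeshift_indel": 0.04,
            "frameshift": 0.06,
            "nonsense": 0.05,
            "splicing": 0.05,
        }
    )
    ancestry_clusters: int = 1
    depth_mean: float = 60.0
    depth_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min < self.maf_max < 0.5):
            raise ValueError("MAF bounds must satisfy 0 < min < max < 0.5")
        total = sum(self.type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")
        if self.causal_genes > self.n_genes:
            raise ValueError("more causal genes than genes")


# ---------------------------------------------------------------------------
# variant- and gene-level building blocks


def _draw_variant_frame(rng: np.random.Generator, gene: str, n_variants: int,
                        cfg: SimConfig) -> pd.DataFrame:
    """Variant metadata for one gene: positions, MAFs, classes, CADD."""
    pos = np.sort(rng.choice(np.arange(1, 500_000), size=n_variants,
                             replace=False)) + 1_000_000
    maf = np.exp(rng.uniform(np.log(cfg.maf_min), np.log(cfg.maf_max),
                             size=n_variants))
    classes = rng.choice(list(cfg.type_probs), size=n_variants,
                         p=list(cfg.type_probs.values()))
    cadd = rng.uniform(*cfg.cadd_benign, size=n_variants)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_variants)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": gene,
            "vclass": classes,
            "cadd": cadd,
            "maf": maf,
            "causal": False,
            "logOR": 0.0,
        }
    )


def _genotypes(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """Hardy-Weinberg additive genotypes, samples x variants."""
    return rng.binomial(2, maf[None, :], size=(n, maf.size)).astype(float)


def plant_causal_variants(frame: pd.DataFrame, indices: np.ndarray,
                          logORs: np.ndarray, cfg: SimConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Mark the given variant rows causal and refresh their CADD scores.

    Causal variants get CADD drawn from the damaging distribution so that
    annotation tracks ground truth the way deleteriousness scores track
    pathogenicity in real panels.  Raises on out-of-range indices or if the
    frame was planted already.
    """
    indices = np.asarray(indices, dtype=int)
    logORs = np.broadcast_to(np.asarray(logORs, dtype=float), indices.shape)
    if frame["causal"].any():
        raise ValueError("region already has planted causal variants")
    if indices.size and (indices.min() < 0 or indices.max() >= len(frame)):
        raise IndexError("causal index out of range")
    out = frame.copy()
    out.loc[out.index[indices], "causal"] = True
    out.loc[out.index[indices], "logOR"] = logORs
    out.loc[out.index[indices], "cadd"] = rng.uniform(
        *cfg.cadd_causal, size=indices.size
    )
    return out


def _region_from_frame(frame: pd.DataFrame, G: np.ndarray,
                       D: Optional[np.ndarray]) -> RegionData:
    variants = [
        VariantRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            gene=str(r.gene), vclass=str(r.vclass), cadd=float(r.cadd),
        )
        for r in frame.itertuples()
    ]
    causal = {
        i: float(lor)
        for i, (c, lor) in enumerate(zip(frame["causal"], frame["logOR"]))
        if c
    }
    return RegionData(gene=str(frame["gene"].iloc[0]), variants=variants,
                      G=G, D=D, causal=causal)


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(cfg: SimConfig) -> tuple[CohortData, list[RegionData], pd.DataFrame]:
    """Simulate an ascertained case-control cohort over ``cfg.n_genes`` genes.

    Returns (cohort, regions, truth) where ``truth`` is a per-variant table
    recording gene, locus, MAF, causal flag and log odds ratio.  Identical
    configurations (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n_var = rng.integers(cfg.variants_min, cfg.variants_max + 1,
                         size=cfg.n_genes)
    frames = [
        _draw_variant_frame(rng, f"GENE{g + 1:03d}", int(n_var[g]), cfg)
        for g in range(cfg.n_genes)
    ]
    causal_gene_idx = rng.choice(cfg.n_genes, size=cfg.causal_genes,
                                 replace=False) if cfg.causal_genes else np.array([], int)
    for g in causal_gene_idx:
        m = len(frames[g])
        k = max(1, int(round(cfg.causal_fraction * m)))
        idx = rng.choice(m, size=k, replace=False)
        frames[g] = plant_causal_variants(frames[g], idx, cfg.causal_logOR,
                                          cfg, rng)

    # --- ascertainment: draw population individuals, keep quota per class
    causal_frames = [frames[g] for g in causal_gene_idx]
    case_G = [np.empty((0, len(f))) for f in causal_frames]
    ctrl_G = [np.empty((0, len(f))) for f in causal_frames]
    n_case = n_ctrl = 0
    batch = max(2000, 4 * (cfg.n_cases + cfg.n_controls))
    for attempt in range(200):
        Gs = [_genotypes(rng, f["maf"].to_numpy(), batch) for f in causal_frames]
        logit = np.full(batch, cfg.baseline_logit)
        for Gc, f in zip(Gs, causal_frames):
            logit += Gc @ f["logOR"].to_numpy()
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        need_case = cfg.n_cases - n_case
        need_ctrl = cfg.n_controls - n_ctrl
        ci = np.flatnonzero(y)[:need_case]
        ki = np.flatnonzero(~y)[:need_ctrl]
        for j in range(len(causal_frames)):
            case_G[j] = np.vstack([case_G[j], Gs[j][ci]])
            ctrl_G[j] = np.vstack([ctrl_G[j], Gs[j][ki]])
        n_case += len(ci)
        n_ctrl += len(ki)
        if n_case >= cfg.n_cases and n_ctrl >= cfg.n_controls:
            break
    else:
        raise AscertainmentError(
            f"could not reach {cfg.n_cases} cases after {attempt + 1} batches; "
            "baseline prevalence too low for the requested quota"
        )

    n = cfg.n_cases + cfg.n_controls
    y = np.concatenate([np.ones(cfg.n_cases), np.zeros(cfg.n_controls)])
    sample_ids = [f"case{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    labels = None
    if cfg.ancestry_clusters > 1:
        labels = [f"pop{rng.integers(cfg.ancestry_clusters) + 1}" for _ in range(n)]
    cohort = CohortData(sample_ids=sample_ids, y=y, X=np.ones((n, 1)),
                        ancestry_label=labels)

    regions: list[RegionData] = []
    causal_pos = {int(g): j for j, g in enumerate(causal_gene_idx)}
    for g, frame in enumerate(frames):
        if g in causal_pos:
            j = causal_pos[g]
            G = np.vstack([case_G[j], ctrl_G[j]])
        else:
            G = _genotypes(rng, frame["maf"].to_numpy(), n)
        D = _depths(rng, G.shape, cfg)
        regions.append(_region_from_frame(frame, G, D))

    truth = pd.concat(frames, ignore_index=True)[
        ["gene", "chrom", "pos", "ref", "alt", "vclass", "cadd", "maf",
         "causal", "logOR"]
    ]
    return cohort, regions, truth


def _depths(rng: np.random.Generator, shape: tuple, cfg: SimConfig) -> np.ndarray:
    """Negative-binomial read depths (gamma-Poisson mixture)."""
    lam = rng.gamma(cfg.depth_dispersion,
                    cfg.depth_mean / cfg.depth_dispersion, size=shape)
    return rng.poisson(lam).astype(int)


def simulate_common_variants(n_samples: int, n_variants: int = 200,
                             n_clusters: int = 3, fst: float = 0.1,
                             seed: int = 0,
                             cluster_sizes: Optional[list[int]] = None
                             ) -> tuple[np.ndarray, list[str]]:
    """Common-variant genotypes with population structure for PCA testing.

    Cluster allele frequencies are drawn around a shared ancestral
    frequency with Balding-Nichols-style drift of magnitude ``fst``.
    Returns (genotype matrix, per-sample cluster labels).
    """
    rng = np.random.default_rng(seed)
    if cluster_sizes is None:
        base = n_samples // n_clusters
        cluster_sizes = [base] * (n_clusters - 1) + [
            n_samples - base * (n_clusters - 1)
        ]
    anc = rng.uniform(0.1, 0.9, size=n_variants)
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    blocks, labels = [], []
    for c, size in enumerate(cluster_sizes):
        freqs = rng.beta(a, b)
        blocks.append(rng.binomial(2, freqs[None, :], size=(size, n_variants)))
        labels += [f"pop{c + 1}"] * size
    return np.vstack(blocks).astype(float), labels


# ---------------------------------------------------------------------------
# the deterministic worked-example fixture


@dataclass
class WorkedExample:
    """Deterministic bundle exercising every downstream stage.

    * ``cohort``/``regions``/``truth`` — a discovery-scale simulation with
      one causal gene among distractors.
    * ``roc_gene`` — a 96-variant gene whose 9 planted pathogenic variants
      (protein-truncating/splicing, high CADD) support ROC calibration of
      the leave-one-out threshold; ``roc_labels`` marks them.
    * ``window_genes`` — 45- and 44-variant genes for window-layout checks.
    * ``gene_sizes`` — 418 per-gene variant counts of which 183 are < 10,
      for the gene-level filter.
    * ``roc_counts`` — per-variant percent-increase values and labels whose
      confusion at the 35% threshold gives 9/9 true positives and 76/86
      true negatives.
    * ``validation`` — a 2x2 carrier table of 41/532 cases vs 32/753
      controls.
    """

    cohort: CohortData
    regions: list[RegionData]
    truth: pd.DataFrame
    roc_gene: RegionData
    roc_labels: np.ndarray
    window_genes: dict
    gene_sizes: np.ndarray
    roc_increases: np.ndarray
    roc_truth: np.ndarray
    validation: ContingencyTable


def make_worked_example(seed: int = 0) -> WorkedExample:
    """Build the deterministic worked-example bundle for the given seed."""
    rng = np.random.default_rng(seed)
    cfg = replace(SimConfig(), seed=int(rng.integers(2 ** 31)),
                  n_genes=8, causal_genes=1)
    cohort, regions, truth = simulate_cohort(cfg)

    # 96-variant calibration gene: 9 planted truncating/splicing variants
    roc_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
    roc_rng = np.random.default_rng(roc_cfg.seed)
    frame = _draw_variant_frame(roc_rng, "ROCGENE", 96, roc_cfg)
    frame["vclass"] = "missense"
    patho_idx = np.sort(roc_rng.choice(96, size=9, replace=False))
    frame = plant_causal_variants(frame, patho_idx, np.log(6.0), roc_cfg,
                                  roc_rng)
    ptv = ["nonsense", "frameshift", "splicing"]
    frame.loc[frame.index[patho_idx], "vclass"] = [
        ptv[i % 3] for i in range(9)
    ]
    G = _ascertained_genotypes(roc_rng, frame, roc_cfg)
    roc_gene = _region_from_frame(frame, G, None)
    roc_labels = frame["causal"].to_numpy()

    window_genes = {}
    for n_v in (45, 44):
        f = _draw_variant_frame(roc_rng, f"WIN{n_v}", n_v, roc_cfg)
        g = _genotypes(roc_rng, f["maf"].to_numpy(),
                       cfg.n_cases + cfg.n_controls)
        window_genes[n_v] = _region_from_frame(f, g, None)

    # 418 genes, 183 with < 10 variants, 235 with >= 10
    sizes = np.concatenate([
        rng.integers(1, 10, size=183),
        rng.integers(10, 100, size=235),
    ])
    rng.shuffle(sizes)

    # percent-increase table reproducing the published confusion at 35%:
    # 9 pathogenic all >= 0.35; of 86 benign, 10 >= 0.35 and 76 below
    inc_patho = rng.uniform(0.40, 1.50, size=9)
    inc_fp = rng.uniform(0.35, 0.80, size=10)
    inc_tn = rng.uniform(0.00, 0.30, size=76)
    roc_increases = np.concatenate([inc_patho, inc_fp, inc_tn])
    roc_truth = np.concatenate([np.ones(9, bool), np.zeros(86, bool)])
    order = rng.permutation(95)
    roc_increases, roc_truth = roc_increases[order], roc_truth[order]

    validation = ContingencyTable(a=41, b=532 - 41, c=32, d=753 - 32)
    return WorkedExample(
        cohort=cohort, regions=regions, truth=truth,
        roc_gene=roc_gene, roc_labels=roc_labels,
        window_genes=window_genes, gene_sizes=sizes,
        roc_increases=roc_increases, roc_truth=roc_truth,
        validation=validation,
    )


def simulate_planted_region(n_variants: int = 40, n_causal: int = 3,
                            causal_within: int = 10,
                            causal_logOR: float = float(np.log(6.0)),
                            causal_maf: tuple[float, float] = (0.003, 0.01),
                            n_cases: int = 400, n_controls: int = 1000,
                            seed: int = 0) -> tuple[RegionData, CohortData]:
    """One ascertained gene with causal variants planted at known indices.

    The causal variants are placed among the first ``causal_within``
    positions with MAF drawn from ``causal_maf`` — the detectable-rare
    band; a causal variant with a single expected carrier cannot be
    localized by any drop-one analysis, so planting in this band makes
    recovery a property of the method rather than of sampling luck.
    The planted indices are recorded in ``region.causal``.
    """
    cfg = SimConfig(n_cases=n_cases, n_controls=n_controls,
                    causal_logOR=causal_logOR, seed=seed)
    rng = np.random.default_rng(seed)
    frame = _draw_variant_frame(rng, "GENE", n_variants, cfg)
    idx = np.sort(rng.choice(causal_within, n_causal, replace=False))
    frame.loc[frame.index[idx], "maf"] = rng.uniform(*causal_maf, n_causal)
    frame = plant_causal_variants(frame, idx, causal_logOR, cfg, rng)
    region = _region_from_frame(
        frame, _ascertained_genotypes(rng, frame, cfg), None
    )
    n = n_cases + n_controls
    cohort = CohortData(
        sample_ids=[f"s{i}" for i in range(n)],
        y=np.concatenate([np.ones(n_cases), np.zeros(n_controls)]),
        X=np.ones((n, 1)),
    )
    return region, cohort


def _ascertained_genotypes(rng: np.random.Generator, frame: pd.DataFrame,
                           cfg: SimConfig) -> np.ndarray:
    """Case-control genotypes for a single gene under its planted effects."""
    maf = frame["maf"].to_numpy()
    lor = frame["logOR"].to_numpy()
    case_rows, ctrl_rows = [], []
    batch = 4 * (cfg.n_cases + cfg.n_controls)
    for _ in range(200):
        G = _genotypes(rng, maf, batch)
        logit = cfg.baseline_logit + G @ lor
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        case_rows.append(G[y][: cfg.n_cases - sum(len(r) for r in case_rows)])
        ctrl_rows.append(G[~y][: cfg.n_controls - sum(len(r) for r in ctrl_rows)])
        if (sum(len(r) for r in case_rows) >= cfg.n_cases
                and sum(len(r) for r in ctrl_rows) >= cfg.n_controls):
            break
    else:
        raise AscertainmentError("case quota unreachable for fixture gene")
    return np.vstack(case_rows + ctrl_rows)
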