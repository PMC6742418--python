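"""Config-driven orchestration of the discovery and validation stages.

Discovery: variant/gene filters -> per-gene region test -> Bonferroni and
Benjamini-Hochberg over the tested-gene family -> leave-one-out
localization of the qualifying genes -> low-CADD disregard and
case/control-driven classification -> deterministic TSV reports.
Validation: unique-carrier counting for one gene in an independent
case-control series, with odds ratio, Wald CI and one-tailed Fisher p.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import loo as loo_mod
from .cohort_io import write_gene_results
from .mist import AnnotationSpec, fit_null_logistic, mist_test
from .qc import FilterConfig, apply_gene_filter, apply_variant_filters
from .stats import ContingencyTable, bh_qvalues, bonferroni_threshold, fisher_exact_or
from .types import CohortData, RegionData

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings shared by the discovery/validation entry points."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    window_size: int = 30
    step: int = 20
    loo_threshold: float = 0.35
    loo_scope: str = "window"
    cadd_disregard: float = 1.0
    alpha: float = 0.05
    known_genes: tuple[str, ...] = ()
    known_gene_alpha: float = 0.05
    seed: int = 0
    outdir: Optional[Path] = None


@dataclass
class DiscoveryReport:
    gene_table: pd.DataFrame
    candidate_table: pd.DataFrame
    window_table: pd.DataFrame
    filter_report: object
    classifications: dict
    bonferroni: float
    manifest: dict


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(map(str, o))
        if isinstance(o, Path):
            return str(o)
        return str(o)

    fields = asdict(cfg)
    fields.pop("outdir", None)  # output location is not an analysis setting
    blob = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_discovery(cohort: CohortData, regions: list[RegionData],
                  cfg: RunConfig | None = None) -> DiscoveryReport:
    """Run the full discovery pipeline on an in-memory study.

    Genes entering the leave-one-out stage are the Bonferroni-significant
    ones plus any configured known susceptibility genes with nominal
    p < ``known_gene_alpha``.  The multiple-testing family is the set of
    genes actually tested, not the pre-filter panel.
    """
    cfg = cfg or RunConfig()
    filtered, filt_report = apply_variant_filters(regions, cohort, cfg.filters)
    tested = apply_gene_filter(filtered, cfg.filters)
    log.info("filters: %d genes in, %d tested (%d variants kept)",
             len(regions), len(tested), filt_report.kept)
    if not tested:
        raise ValueError("no gene survives the filters")

    null_fit = fit_null_logistic(cohort.y, cohort.X)
    results = [
        mist_test(r, cohort, cfg.annotation, null_fit=null_fit)
        for r in tested
    ]
    m = len(results)
    pvals = np.array([r.p_overall for r in results])
    qvals = bh_qvalues(pvals, m=m)
    bonf = bonferroni_threshold(cfg.alpha, m)
    gene_table = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_variants": [r.n_variants for r in results],
            "S_pi": [r.S_pi for r in results],
            "p_pi": [r.p_pi for r in results],
            "S_tau": [r.S_tau for r in results],
            "p_tau": [r.p_tau for r in results],
            "p": pvals,
            "q": qvals,
            "bonferroni_significant": pvals <= bonf,
            "warnings": [";".join(r.warnings) for r in results],
        }
    )

    to_loo = [
        r for r, p in zip(tested, pvals)
        if p <= bonf
        or (r.gene in cfg.known_genes and p < cfg.known_gene_alpha)
    ]
    window_rows, cand_rows, classifications = [], [], {}
    for region in to_loo:
        windows = loo_mod.build_windows(region.n_variants, cfg.window_size,
                                        cfg.step)
        scan = loo_mod.loo_window_scan(region, cohort, cfg.annotation,
                                       windows, null_fit=null_fit)
        for w in scan:
            window_rows.append(
                {
                    "gene": region.gene, "start": w.start, "end": w.end,
                    "p_full": w.p_full, "p_drop": w.p_drop,
                    "neg_log10_p_drop": (
                        -np.log10(w.p_drop) if w.p_drop else np.nan
                    ),
                    "flagged": w.flagged, "unevaluable": w.unevaluable,
                }
            )
        flagged = [w for w in scan if w.flagged]
        var_results = loo_mod.loo_variant_scan(
            region, cohort, flagged, cfg.annotation,
            threshold=cfg.loo_threshold, scope=cfg.loo_scope,
            cadd_disregard=cfg.cadd_disregard, null_fit=null_fit,
        )
        cands = loo_mod.candidate_variants(var_results)
        if cands:
            cls = loo_mod.classify_candidates(cands, region.G, cohort.y)
            classifications[region.gene] = cls
        controls = cohort.y == 0
        cases = cohort.y == 1
        for r in cands:
            gcol = np.nan_to_num(region.G[:, r.index])
            case_maf = gcol[cases].sum() / (2 * cases.sum())
            ctrl_maf = gcol[controls].sum() / (2 * controls.sum())
            cand_rows.append(
                {
                    "gene": region.gene,
                    "chrom": r.variant.chrom,
                    "pos": r.variant.pos,
                    "ref": r.variant.ref,
                    "alt": r.variant.alt,
                    "vclass": r.variant.vclass,
                    "cadd": r.variant.cadd,
                    "case_maf": case_maf,
                    "control_maf": ctrl_maf,
                    "pct_increase": r.pct_increase_display,
                }
            )

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_genes_input": len(regions),
        "n_genes_tested": m,
        "bonferroni_threshold": bonf,
        "n_genes_loo": len(to_loo),
    }
    report = DiscoveryReport(
        gene_table=gene_table,
        candidate_table=pd.DataFrame(cand_rows),
        window_table=pd.DataFrame(window_rows),
        filter_report=filt_report,
        classifications=classifications,
        bonferroni=bonf,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        _write_reports(report, Path(cfg.outdir))
    return report


def _write_reports(report: DiscoveryReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_results(report.gene_table, outdir / "gene_results.tsv")
    report.candidate_table.to_csv(outdir / "candidate_variants.tsv",
                                  sep="\t", index=False, float_format="%.12g")
    report.window_table.to_csv(outdir / "loo_windows.tsv", sep="\t",
                               index=False, float_format="%.12g")
    report.filter_report.to_frame().to_csv(outdir / "filter_counts.tsv",
                                           sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True)
    )


@dataclass
class ValidationReport:
    gene: str
    table: ContingencyTable
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    haldane_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "case_carriers": t.a, "case_total": t.n_cases,
                    "control_carriers": t.c, "control_total": t.n_controls,
                    "case_fraction": t.case_carrier_fraction,
                    "control_fraction": t.control_carrier_fraction,
                    "OR": self.oddsratio, "ci_low": self.ci_low,
                    "ci_high": self.ci_high, "p_one_tailed": self.p,
                    "haldane_corrected": self.haldane_corrected,
                }
            ]
        )


def run_validation(cohort: CohortData, regions: list[RegionData], gene: str,
                   cfg: RunConfig | None = None) -> ValidationReport:
    """Carrier-level validation of one gene in an independent series.

    Counts unique carriers of qualifying (post-filter, nonsynonymous)
    variants per group and tests enrichment in cases with a one-tailed
    Fisher's exact test.
    """
    cfg = cfg or RunConfig()
    matching = [r for r in regions if r.gene == gene]
    if not matching:
        raise KeyError(f"gene {gene!r} absent from the validation table")
    filtered, _ = apply_variant_filters(matching, cohort, cfg.filters)
    region = filtered[0]
    carrier = (
        np.nansum(region.G, axis=1) > 0
        if region.n_variants
        else np.zeros(cohort.n, dtype=bool)
    )
    a = int(carrier[cohort.y == 1].sum())
    c = int(carrier[cohort.y == 0].sum())
    t = ContingencyTable(a=a, b=cohort.n_cases - a, c=c,
                         d=cohort.n_controls - c)
    res = fisher_exact_or(t, sided="one")
    return ValidationReport(
        gene=gene, table=t, oddsratio=res.oddsratio, ci_low=res.ci_low,
        ci_high=res.ci_high, p=res.p, haldane_corrected=res.haldane_corrected,
    )


def validation_from_counts(a: int, n_cases: int, c: int, n_controls: int,
                           gene: str = "") -> ValidationReport:
    """Validation statistics straight from published carrier counts."""
    t = ContingencyTable(a=a, b=n_cases - a, c=c, d=n_controls - c)
    res = fisher_exact_or(t, sided="one")
    return ValidationReport(
        gene=gene, table=t, oddsratio=res.oddsratio, ci_low=res.ci_low,
        ci_high=res.ci_high, p=res.p, haldane_corrected=res.haldane_corrected,
    )
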