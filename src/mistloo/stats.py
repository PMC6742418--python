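"""Multiple-testing correction, validation contingency statistics and the
design-stage two-proportion sample-size calculation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def case_carrier_fraction(self) -> float:
        return self.a / self.n_cases

    @property
    def control_carrier_fraction(self) -> float:
        return self.c / self.n_controls


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    haldane_corrected: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the two-proportion sample-size calculation.

    Defaults describe a search for genes carrying pathogenic variants in at
    least 3% of cases versus 0.1% of unaffected individuals, two controls
    per case, at a Bonferroni-corrected one-sided significance level for a
    445-gene panel and 80% power.
    """

    p1: float = 0.03
    p2: float = 0.001
    ratio: float = 2.0
    alpha: float = 0.000112
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.p2 < self.p1 < 1.0):
            raise ValueError("need 0 < p2 < p1 < 1")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def bh_qvalues(p: np.ndarray, m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` is the size of the test family and may exceed ``len(p)`` when
    only a subset of the family's p-values is available (e.g. a published
    table truncated at p <= 0.05); the unobserved tests are assumed large
    enough not to enter the step-up cumulative minimum, which holds
    whenever every unobserved p exceeds every observed one.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ValueError("family size m cannot be smaller than len(p)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_or(t: ContingencyTable, sided: str = "one") -> OddsRatioResult:
    """Odds ratio with Wald 95% CI and Fisher's exact p for a 2x2 table.

    The one-sided alternative tests carrier *enrichment in cases*.  When a
    cell is zero, the Haldane-Anscombe +0.5 correction is applied to the
    OR and its interval (flagged in the result); the exact p is always
    computed on the raw counts.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
    oddsratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.975)
    lo, hi = np.exp(np.log(oddsratio) + np.array([-z, z]) * se)
    alternative = "greater" if sided == "one" else "two-sided"
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    return OddsRatioResult(
        oddsratio=float(oddsratio), ci_low=float(lo), ci_high=float(hi),
        p=float(p), haldane_corrected=corrected,
    )


def allele_frequency(alt_alleles: int, total_alleles: int) -> float:
    """Simple allele frequency alt/total."""
    if total_alleles < 1:
        raise ValueError("total allele count must be >= 1")
    if not (0 <= alt_alleles <= total_alleles):
        raise ValueError("alt allele count outside [0, total]")
    return alt_alleles / total_alleles


def two_prop_sample_size(spec: PowerSpec, sided: str = "one") -> tuple[int, int]:
    """Smallest (n_cases, n_controls) reaching the target power.

    Uses the pooled-variance normal approximation for the difference of two
    independent proportions with unequal allocation (``ratio`` controls per
    case).  :func:`simulate_two_prop_power` provides the companion
    Monte-Carlo check at the returned size.
    """
    p1, p2, k = spec.p1, spec.p2, spec.ratio
    alpha = spec.alpha if sided == "one" else spec.alpha / 2.0
    za = sps.norm.isf(alpha)
    zb = sps.norm.isf(1.0 - spec.power)
    pbar = (p1 + k * p2) / (1.0 + k)
    qbar = 1.0 - pbar
    num = za * np.sqrt((1.0 + 1.0 / k) * pbar * qbar) + zb * np.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2) / k
    )
    n1 = int(np.ceil((num / (p1 - p2)) ** 2))
    return n1, int(np.ceil(k * n1))


def two_prop_power(n_cases: int, n_controls: int, spec: PowerSpec,
                   sided: str = "one") -> float:
    """Normal-approximation power of the pooled two-proportion Z test.

    This is the analytic counterpart of :func:`two_prop_sample_size`; the
    Monte-Carlo check (:func:`simulate_two_prop_power`) can exceed it
    noticeably when the comparison proportion is very small, where the
    normal approximation to the binomial is conservative.
    """
    p1, p2 = spec.p1, spec.p2
    alpha = spec.alpha if sided == "one" else spec.alpha / 2.0
    zcrit = sps.norm.isf(alpha)
    pbar = (n_cases * p1 + n_controls * p2) / (n_cases + n_controls)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n_cases + 1 / n_controls))
    se1 = np.sqrt(p1 * (1 - p1) / n_cases + p2 * (1 - p2) / n_controls)
    return float(sps.norm.sf((zcrit * se0 - (p1 - p2)) / se1))


def simulate_two_prop_power(n_cases: int, n_controls: int, spec: PowerSpec,
                            n_rep: int = 20_000, seed: int = 0,
                            sided: str = "one") -> float:
    """Monte-Carlo power of the pooled two-proportion Z test at a given size."""
    rng = np.random.default_rng(seed)
    alpha = spec.alpha if sided == "one" else spec.alpha / 2.0
    zcrit = sps.norm.isf(alpha)
    x1 = rng.binomial(n_cases, spec.p1, size=n_rep)
    x2 = rng.binomial(n_controls, spec.p2, size=n_rep)
    ph1, ph2 = x1 / n_cases, x2 / n_controls
    pbar = (x1 + x2) / (n_cases + n_controls)
    se = np.sqrt(pbar * (1 - pbar) * (1 / n_cases + 1 / n_controls))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ph1 - ph2) / se
    return float(np.mean(z >= zcrit))
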