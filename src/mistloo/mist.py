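"""Mixed-effects score test (MiST) for region-based rare-variant association.

The model for a region with m variants is a hierarchical logistic regression

    logit P(y_i = 1) = x_i' alpha + g_i' beta,      beta = Z pi + b,

where ``g_i`` is the vector of alt-allele dosages, ``Z`` (m x q) carries
per-variant annotations (intercept, scaled CADD, consequence-class
indicators) and ``b`` are residual per-variant effects with variance tau.
Two score tests are formed:

* the *burden* test of the annotation-driven fixed effect pi, a Rao score
  test of adding the burden matrix ``B = G Z`` to the covariate-only null
  model (chi-square with q degrees of freedom);
* the *variance-component* test of tau, computed from the residuals of the
  pi-model (logistic fit of y on X and B); its null distribution is a
  weighted mixture of one-degree chi-squares.

The two p-values are asymptotically independent and are combined with
Fisher's method on 4 degrees of freedom to give the region p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate
from scipy import linalg
from scipy import stats

from .types import CohortData, RegionData

P_FLOOR = 1e-300

__all__ = [
    "AnnotationSpec",
    "MistResult",
    "NullFit",
    "build_annotation",
    "fit_null_logistic",
    "burden_component",
    "variance_component",
    "fisher_combine",
    "mist_test",
    "chi2_mixture_sf",
]


class DegeneratePhenotypeError(ValueError):
    """Phenotype has a single class; the logistic null model is undefined."""


class DegenerateRegionError(ValueError):
    """The burden matrix carries no information (e.g. all-zero genotypes)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (e.g. perfect separation)."""


# ---------------------------------------------------------------------------
# annotation design matrix


@dataclass(frozen=True)
class AnnotationSpec:
    """How to build the variant annotation matrix Z for a region.

    Z gets an intercept column (every variant contributes to the plain
    burden), a CADD column (z-scored within the region by default, so the
    burden weighting is relative deleteriousness) and one-hot consequence
    columns for {frameshift, nonframeshift_indel, nonsense, splicing} with
    missense as the reference class.  Constant or collinear columns are
    pruned with a warning before testing.
    """

    use_cadd: bool = True
    use_type: bool = True
    include_intercept: bool = True
    cadd_scaling: str = "zscore"  # "zscore" | "none"

    TYPE_LEVELS = ("frameshift", "nonframeshift_indel", "nonsense", "splicing")


def build_annotation(region: RegionData, spec: AnnotationSpec) -> tuple[np.ndarray, list[str]]:
    """Return (Z, column_names) for a region; Z has one row per variant.

    Missing CADD scores are imputed to the within-region mean before
    scaling.  Degenerate-column pruning happens later, at test time, so the
    returned matrix always reflects the requested encoding.
    """
    m = region.n_variants
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones(m))
        names.append("intercept")
    if spec.use_cadd:
        cadd = np.array(
            [np.nan if v.cadd is None else float(v.cadd) for v in region.variants]
        )
        if np.isnan(cadd).all():
            cadd = np.zeros(m)
        else:
            cadd = np.where(np.isnan(cadd), np.nanmean(cadd), cadd)
        if spec.cadd_scaling == "zscore":
            sd = cadd.std()
            cadd = (cadd - cadd.mean()) / sd if sd > 0 else np.zeros(m)
        cols.append(cadd)
        names.append("cadd")
    if spec.use_type:
        classes = np.array([v.vclass for v in region.variants])
        for level in AnnotationSpec.TYPE_LEVELS:
            cols.append((classes == level).astype(float))
            names.append(f"type_{level}")
    if not cols:
        raise ValueError("annotation spec produced an empty Z")
    return np.column_stack(cols), names


def _prune_columns(M: np.ndarray, names: list[str], keep_first: bool = True):
    """Drop constant-zero and linearly dependent columns; report what was cut."""
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(M.shape[1]):
        cand = M[:, kept + [j]]
        if not np.any(M[:, j]):
            dropped.append(names[j])
            continue
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            dropped.append(names[j])
    return M[:, kept], [names[i] for i in kept], dropped


# ---------------------------------------------------------------------------
# logistic null model


@dataclass
class NullFit:
    """Maximum-likelihood logistic fit of y on a design matrix M."""

    coef: np.ndarray
    mu: np.ndarray
    M: np.ndarray
    y: np.ndarray
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu


def _irls_logistic(y: np.ndarray, M: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> NullFit:
    """Iteratively reweighted least squares; converges on score norm <= tol."""
    n, p = M.shape
    beta = np.zeros(p)
    # start the intercept at the empirical log-odds for faster convergence
    ybar = y.mean()
    if 0.0 < ybar < 1.0 and np.allclose(M[:, 0], 1.0):
        beta[0] = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        eta = np.clip(M @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = M.T @ (y - mu)
        if np.linalg.norm(score, ord=np.inf) <= tol:
            return NullFit(coef=beta, mu=mu, M=M, y=y)
        info = (M * w[:, None]).T @ M
        try:
            step = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # halve steps that do not improve the log-likelihood (separation guard)
        ll0 = _loglik(y, M, beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _loglik(y, M, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
    raise ConvergenceError(
        "logistic IRLS did not converge (possible perfect separation); "
        f"final score norm {np.linalg.norm(score, ord=np.inf):.3g}"
    )


def _loglik(y, M, beta):
    eta = np.clip(M @ beta, -30, 30)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_null_logistic(y: np.ndarray, X: np.ndarray) -> NullFit:
    """Fit the covariate-only logistic null model.

    Raises :class:`DegeneratePhenotypeError` when y is single-class and
    :class:`ConvergenceError` on non-convergence (perfect separation).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() == y.max():
        raise DegeneratePhenotypeError(
            "phenotype has a single class; cannot fit logistic null model"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return _irls_logistic(y, X)


# ---------------------------------------------------------------------------
# score tests


@dataclass
class BurdenResult:
    S_pi: float
    df: int
    p_pi: float
    pi_fit: NullFit
    dropped_columns: list[str] = field(default_factory=list)


def _score_test(null_fit: NullFit, A: np.ndarray) -> tuple[float, int, float]:
    """Rao score test of adding columns A to a fitted logistic model.

    Returns (statistic, df, p).  The information matrix is partitioned as
    usual; the effective df is the rank of the conditional information, so
    collinearity with the null design costs degrees of freedom rather than
    producing a singular solve.
    """
    M, w, r = null_fit.M, null_fit.weights, null_fit.residuals
    U = A.T @ r
    Iaa = (A * w[:, None]).T @ A
    Iam = (A * w[:, None]).T @ M
    Imm = (M * w[:, None]).T @ M
    V = Iaa - Iam @ linalg.solve(Imm, Iam.T, assume_a="pos")
    # symmetric pseudo-inverse keeps the statistic well-defined when A is
    # nearly collinear with M
    Vinv = np.linalg.pinv((V + V.T) / 2.0, rcond=1e-10)
    S = float(U @ Vinv @ U)
    df = int(np.linalg.matrix_rank((V + V.T) / 2.0, tol=1e-10))
    if df == 0:
        raise DegenerateRegionError("score test has zero effective df")
    p = float(stats.chi2.sf(S, df))
    return max(S, 0.0), df, max(p, P_FLOOR)


def burden_component(null_fit: NullFit, G: np.ndarray, Z: np.ndarray,
                     z_names: Optional[list[str]] = None) -> BurdenResult:
    """Burden score test of the annotation-weighted genotype matrix B = G Z.

    ``G`` must already have missing entries imputed.  Degenerate columns of
    B (all-zero or collinear) are pruned; the test is chi-square with the
    remaining column count as df.  Raises :class:`DegenerateRegionError`
    when B carries no information at all.
    """
    names = z_names or [f"z{j}" for j in range(Z.shape[1])]
    B = G @ Z
    B, kept_names, dropped = _prune_columns(B, names)
    if B.shape[1] == 0:
        raise DegenerateRegionError(
            "burden matrix is identically zero; region is untestable"
        )
    S, df, p = _score_test(null_fit, B)
    pi_design = np.column_stack([null_fit.M, B])
    pi_fit = _irls_logistic(null_fit.y, pi_design)
    return BurdenResult(S_pi=S, df=df, p_pi=p, pi_fit=pi_fit,
                        dropped_columns=dropped)


def variance_component(pi_fit: NullFit, G: np.ndarray) -> tuple[float, np.ndarray, float, str]:
    """Variance-component score test of residual per-variant effects.

    S_tau = r' G G' r with r the pi-model residuals; under the null S_tau
    is distributed as sum_k lambda_k chi2_1 where lambda_k are the nonzero
    eigenvalues of G' P G and P = W - W M (M' W M)^-1 M' W is the
    information-projection of the pi-model design M.

    Returns (S_tau, lambdas, p_tau, tail_method).
    """
    M, w, r = pi_fit.M, pi_fit.weights, pi_fit.residuals
    S_tau = float(np.sum((G.T @ r) ** 2))
    WM = M * w[:, None]
    GW = G * w[:, None]
    GtPG = GW.T @ G - (G.T @ WM) @ linalg.solve(WM.T @ M, WM.T @ G, assume_a="pos")
    GtPG = (GtPG + GtPG.T) / 2.0
    lam = linalg.eigvalsh(GtPG)
    lam = lam[lam > max(lam.max(), 0.0) * 1e-10] if lam.size else lam
    if lam.size == 0 or S_tau <= 0.0:
        return max(S_tau, 0.0), lam, 1.0, "boundary"
    p, method = chi2_mixture_sf(S_tau, lam)
    return S_tau, lam, max(min(p, 1.0), P_FLOOR), method


# ---------------------------------------------------------------------------
# chi-square mixture tail


def chi2_mixture_sf(x: float, lam: np.ndarray) -> tuple[float, str]:
    """Upper tail P(sum_k lam_k chi2_1 > x) for positive weights ``lam``.

    The exact tail is computed by numerical inversion of the characteristic
    function (Imhof's integral) to absolute accuracy ~1e-9, falling back to
    Liu's three-moment chi-square approximation if the quadrature fails or
    returns a non-positive value.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.size == 1:
        return float(stats.chi2.sf(x / lam[0], df=1)), "exact1"
    try:
        p = _imhof_sf(x, lam)
        if np.isfinite(p) and 0.0 < p <= 1.0:
            return p, "imhof"
    except Exception:  # quadrature failure -> moment matching
        pass
    return _liu_sf(x, lam), "liu"


def _imhof_sf(x: float, lam: np.ndarray) -> float:
    def theta(u):
        return 0.5 * np.sum(np.arctan(lam[:, None] * u), axis=0) - 0.5 * x * u

    def rho(u):
        return np.exp(0.25 * np.sum(np.log1p((lam[:, None] * u) ** 2), axis=0))

    def integrand(u):
        u = np.atleast_1d(u)
        return np.sin(theta(u)) / (u * rho(u))

    val, err = integrate.quad(lambda u: float(integrand(u)[0]), 0.0, np.inf,
                              limit=500, epsabs=1e-11, epsrel=1e-9)
    if err > 1e-6:
        raise RuntimeError(f"Imhof quadrature error too large: {err:.2g}")
    return 0.5 + val / np.pi


def _liu_sf(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang three-moment chi-square approximation to the tail."""
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * a
    t = (x - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, delta)) if delta > 0 else float(
        stats.chi2.sf(t, df)
    )


# ---------------------------------------------------------------------------
# combination and orchestration


def fisher_combine(p_pi: float, p_tau: float) -> float:
    """Fisher's combination of the two component p-values (chi-square, 4 df)."""
    if p_pi <= 0 or p_tau <= 0 or p_pi > 1 or p_tau > 1:
        raise ValueError("component p-values must lie in (0, 1]")
    T = -2.0 * (np.log(p_pi) + np.log(p_tau))
    return max(float(stats.chi2.sf(T, df=4)), P_FLOOR)


@dataclass
class MistResult:
    """Burden, variance-component and combined statistics for one region."""

    gene: str
    S_pi: float
    df_pi: int
    p_pi: float
    S_tau: float
    lambdas: np.ndarray
    p_tau: float
    p_overall: float
    n_variants: int
    warnings: list[str] = field(default_factory=list)


def impute_missing(G: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-variant non-missing mean.

    Columns that are entirely missing become zero (monomorphic).
    """
    G = np.asarray(G, dtype=float)
    if not np.isnan(G).any():
        return G
    out = G.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(out, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def mist_test(region: RegionData, cohort: CohortData,
              spec: AnnotationSpec | None = None,
              null_fit: NullFit | None = None) -> MistResult:
    """Run the full mixed-effects score test on one gene region.

    ``null_fit`` may be supplied to reuse the covariate-only fit across
    genes (it depends only on the cohort).  The result is deterministic:
    there is no internal randomness.
    """
    spec = spec or AnnotationSpec()
    if null_fit is None:
        null_fit = fit_null_logistic(cohort.y, cohort.X)
    G = impute_missing(region.G)
    Z, z_names = build_annotation(region, spec)
    notes: list[str] = []
    burden = burden_component(null_fit, G, Z, z_names)
    if burden.dropped_columns:
        notes.append("pruned Z columns: " + ",".join(burden.dropped_columns))
    S_tau, lam, p_tau, method = variance_component(burden.pi_fit, G)
    if method == "liu":
        notes.append("variance-component tail used Liu fallback")
    p_overall = fisher_combine(burden.p_pi, p_tau)
    return MistResult(
        gene=region.gene,
        S_pi=burden.S_pi,
        df_pi=burden.df,
        p_pi=burden.p_pi,
        S_tau=S_tau,
        lambdas=lam,
        p_tau=p_tau,
        p_overall=p_overall,
        n_variants=region.n_variants,
        warnings=notes,
    )
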