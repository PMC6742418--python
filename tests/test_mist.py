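"""Mixed-effects score test: closed forms, oracles and invariances."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import balanced_cohort, random_region
from mistloo.mist import (
    AnnotationSpec,
    DegeneratePhenotypeError,
    DegenerateRegionError,
    burden_component,
    chi2_mixture_sf,
    fisher_combine,
    fit_null_logistic,
    mist_test,
    variance_component,
)
from mistloo.types import CohortData


class TestNullFit:
    def test_intercept_only_closed_form(self):
        y = np.concatenate([np.ones(30), np.zeros(70)])
        fit = fit_null_logistic(y, np.ones((100, 1)))
        np.testing.assert_allclose(fit.mu, 0.30, atol=1e-10)
        assert fit.coef[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_single_class_raises(self):
        with pytest.raises(DegeneratePhenotypeError):
            fit_null_logistic(np.ones(10), np.ones((10, 1)))

    def test_binary_covariate_equals_2x2_log_odds(self):
        """With one binary covariate the MLE slope is the table log-OR."""
        rng = np.random.default_rng(0)
        x = rng.binomial(1, 0.4, 500).astype(float)
        y = rng.binomial(1, np.where(x > 0, 0.6, 0.3)).astype(float)
        a = ((y == 1) & (x == 1)).sum()
        b = ((y == 0) & (x == 1)).sum()
        c = ((y == 1) & (x == 0)).sum()
        d = ((y == 0) & (x == 0)).sum()
        fit = fit_null_logistic(y, np.column_stack([np.ones(500), x]))
        assert fit.coef[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-7)


class TestBurden:
    def test_q1_equals_statsmodels_score_test(self):
        """With Z = 1 the burden test is the textbook logistic score test
        on the carrier-burden sum; statsmodels is the independent oracle."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 200
            y = rng.binomial(1, 0.4, n).astype(float)
            G = rng.binomial(2, 0.05, (n, 8)).astype(float)
            X = np.ones((n, 1))
            nf = fit_null_logistic(y, X)
            ours = burden_component(nf, G, np.ones((8, 1)), ["i"])
            m0 = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            out = m0.model.score_test(m0.params, exog_extra=G.sum(1)[:, None])
            p_oracle = float(np.asarray(out[1]).ravel()[0])
            assert ours.p_pi == pytest.approx(p_oracle, abs=1e-8)

    def test_all_zero_genotypes_raise(self):
        nf = fit_null_logistic(
            np.concatenate([np.ones(5), np.zeros(5)]), np.ones((10, 1))
        )
        with pytest.raises(DegenerateRegionError):
            burden_component(nf, np.zeros((10, 4)), np.ones((4, 1)), ["i"])

    def test_stronger_burden_gives_smaller_p(self):
        """Median burden p over seeded replicates is smaller at OR 3 than
        under the null (OR 1)."""
        def median_p(log_or, seed):
            rng = np.random.default_rng(seed)
            ps = []
            for _ in range(40):
                n = 200
                G = rng.binomial(2, 0.02, (n, 10)).astype(float)
                eta = -0.5 + log_or * G.sum(1)
                y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
                if y.min() == y.max():
                    continue
                nf = fit_null_logistic(y, np.ones((n, 1)))
                ps.append(burden_component(nf, G, np.ones((10, 1)), ["i"]).p_pi)
            return np.median(ps)

        assert median_p(np.log(3.0), 11) < median_p(0.0, 11)


class TestVarianceComponent:
    def test_orthogonal_residuals_give_zero(self):
        """Residuals of the pi-model are orthogonal to B's span: with a
        single variant B spans G, so S_tau = 0 and p_tau = 1."""
        rng = np.random.default_rng(2)
        y = rng.binomial(1, 0.3, 300).astype(float)
        G = rng.binomial(2, 0.1, (300, 1)).astype(float)
        nf = fit_null_logistic(y, np.ones((300, 1)))
        br = burden_component(nf, G, np.ones((1, 1)), ["i"])
        S, lam, p, _ = variance_component(br.pi_fit, G)
        assert S == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_single_variant_closed_form(self):
        """Against a covariate-only fit, a single-variant S_tau follows
        lambda * chi2_1 exactly."""
        rng = np.random.default_rng(3)
        y = rng.binomial(1, 0.3, 400).astype(float)
        G = rng.binomial(2, 0.1, (400, 1)).astype(float)
        nf = fit_null_logistic(y, np.ones((400, 1)))
        S, lam, p, _ = variance_component(nf, G)
        assert lam.size == 1
        assert p == pytest.approx(float(sps.chi2.sf(S / lam[0], 1)), rel=1e-9)

    def test_tail_against_permutation(self):
        """Asymptotic p_tau within 3 Monte-Carlo SEs of a 500-permutation p
        at a sample size where the asymptotics hold."""
        from mistloo.mist import _irls_logistic

        seed, n, nperm = 1, 800, 500
        rng = np.random.default_rng(seed)
        y = rng.permutation(
            np.concatenate([np.ones(n // 3), np.zeros(n - n // 3)])
        )
        X = np.ones((n, 1))
        maf = np.exp(rng.uniform(np.log(0.05), np.log(0.2), 20))
        G = rng.binomial(2, maf, (n, 20)).astype(float)
        nf = fit_null_logistic(y, X)
        Z = np.column_stack([np.ones(20), rng.normal(size=20)])
        br = burden_component(nf, G, Z, ["i", "c"])
        S, lam, p, _ = variance_component(br.pi_fit, G)
        B = G @ Z
        prng = np.random.default_rng(seed + 1000)
        cnt = 0
        for _ in range(nperm):
            yp = prng.permutation(y)
            fitp = _irls_logistic(yp, np.column_stack([X, B]))
            cnt += float(np.sum((G.T @ fitp.residuals) ** 2)) >= S
        pperm = (cnt + 1) / (nperm + 1)
        se = np.sqrt(pperm * (1 - pperm) / nperm)
        assert abs(p - pperm) <= 3 * se


class TestMixtureTail:
    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(4)
        lam = rng.uniform(0.2, 3.0, 10)
        sim = (rng.chisquare(1, (100_000, 10)) * lam).sum(1)
        for q in (0.5, 0.9, 0.99):
            x = np.quantile(sim, q)
            p, _ = chi2_mixture_sf(x, lam)
            assert p == pytest.approx(1 - q, abs=4 * np.sqrt(q * (1 - q) / 1e5))

    def test_liu_fallback_in_far_tail(self):
        lam = np.array([1.0, 0.5, 0.2])
        p, method = chi2_mixture_sf(500.0, lam)
        assert 0 < p < 1e-50


class TestFisherCombine:
    @pytest.mark.parametrize(
        "p_pi,p_tau,expected",
        [
            (1.0, 1.0, 1.0),
            # closed form exp(-T/2)(1+T/2) with T = -2 ln(p_pi p_tau)
            (0.5, 0.5, 0.25 * (1 + 2 * np.log(2))),
            (0.01, 0.02, np.exp(np.log(2e-4) ) * (1 - np.log(2e-4))),
        ],
    )
    def test_closed_form(self, p_pi, p_tau, expected):
        assert fisher_combine(p_pi, p_tau) == pytest.approx(expected, rel=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_combine(0.0, 0.5)


class TestMistTest:
    def test_all_missense_prunes_type_columns_with_warning(self, small_cohort):
        rng = np.random.default_rng(5)
        region = random_region(rng, small_cohort.n, 15, maf_hi=0.05)
        for i, v in enumerate(region.variants):
            region.variants[i] = type(v)(
                v.chrom, v.pos, v.ref, v.alt, v.gene, "missense", v.cadd
            )
        res = mist_test(region, small_cohort)
        assert any("pruned" in w for w in res.warnings)
        assert 0 < res.p_overall <= 1

    def test_invariant_to_sample_order(self, small_cohort):
        rng = np.random.default_rng(6)
        region = random_region(rng, small_cohort.n, 12, maf_hi=0.05)
        base = mist_test(region, small_cohort)
        perm = rng.permutation(small_cohort.n)
        cohort_p = CohortData(
            [small_cohort.sample_ids[i] for i in perm],
            small_cohort.y[perm], small_cohort.X[perm],
        )
        region_p = type(region)(
            region.gene, region.variants, region.G[perm], None
        )
        res = mist_test(region_p, cohort_p)
        assert res.p_overall == pytest.approx(base.p_overall, rel=1e-9)
        assert res.p_pi == pytest.approx(base.p_pi, rel=1e-9)

    def test_deterministic(self, small_cohort):
        rng = np.random.default_rng(7)
        region = random_region(rng, small_cohort.n, 12, maf_hi=0.05)
        r1 = mist_test(region, small_cohort)
        r2 = mist_test(region, small_cohort)
        assert (r1.p_pi, r1.p_tau, r1.p_overall) == (r2.p_pi, r2.p_tau,
                                                     r2.p_overall)

    def test_causal_gene_beats_null_sibling(self):
        """Paired simulation: a gene with 5/20 variants at OR 5 attains a
        smaller region p than its matched null gene in >= 95/100 replicates."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 600
            maf = np.exp(rng.uniform(np.log(1e-3), np.log(0.01), 20))
            idx = rng.choice(20, 5, replace=False)
            # causal variants in the detectable-rare band (>= a few carriers)
            maf[idx] = rng.uniform(0.003, 0.01, 5)
            G_causal = rng.binomial(2, maf, (n, 20)).astype(float)
            G_null = rng.binomial(2, maf, (n, 20)).astype(float)
            eta = -1.0 + np.log(5.0) * G_causal[:, idx].sum(1)
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() < 10 or y.sum() > n - 10:
                continue
            cohort = CohortData([f"s{i}" for i in range(n)], y,
                                np.ones((n, 1)))
            rc = random_region(rng, n, 20)
            rc.G = G_causal
            rn = random_region(rng, n, 20)
            rn.G = G_null
            pc = mist_test(rc, cohort).p_overall
            pn = mist_test(rn, cohort).p_overall
            wins += pc < pn
        assert wins >= 0.95 * n_rep

    def test_null_pvalues_uniform_at_study_scale(self):
        """Kolmogorov-Smirnov does not reject uniformity of the region p
        under the null at the discovery cohort scale."""
        n = 1385
        cohort = balanced_cohort(398, 987)
        rng = np.random.default_rng(42)
        from mistloo.mist import fit_null_logistic as _fnl

        nf = _fnl(cohort.y, cohort.X)
        ps = []
        for _ in range(250):
            region = random_region(rng, n, 20)
            ps.append(mist_test(region, cohort, null_fit=nf).p_overall)
        assert sps.kstest(ps, "uniform").pvalue > 0.01
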