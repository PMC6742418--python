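"""Run the mixed-effects score test on one simulated gene region.

Builds a small case-control cohort with one causal gene planted among
distractors, then tests each gene and prints its burden, variance-component
and combined p-values.
"""

from mistloo import SimConfig, mist_test, simulate_cohort

cfg = SimConfig(n_cases=200, n_controls=400, n_genes=4, causal_genes=1,
                seed=1)
cohort, regions, truth = simulate_cohort(cfg)
causal_gene = truth.loc[truth.causal, "gene"].iloc[0]

print(f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls")
print(f"planted causal gene: {causal_gene}\n")
print(f"{'gene':10s} {'m':>3s} {'p_burden':>10s} {'p_variance':>10s} "
      f"{'p_overall':>10s}")
for region in regions:
    r = mist_test(region, cohort)
    print(f"{r.gene:10s} {r.n_variants:3d} {r.p_pi:10.3g} {r.p_tau:10.3g} "
          f"{r.p_overall:10.3g}")

print("\nThe causal gene should show the smallest combined p: the burden "
      "component captures the shared risk direction of its planted "
      "variants and Fisher's combination folds in any residual "
      "per-variant heterogeneity.")
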