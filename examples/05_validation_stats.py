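"""Validation-series statistics for a candidate gene.

Given carrier counts in an independent case-control series (41 of 532
familial cases vs 32 of 753 controls), computes the odds ratio, its Wald
95% interval and the one-tailed Fisher exact p for enrichment in cases.
"""

from mistloo.pipeline import validation_from_counts

report = validation_from_counts(a=41, n_cases=532, c=32, n_controls=753,
                                gene="CANDIDATE")
t = report.table
print(f"case carriers:    {t.a}/{t.n_cases} "
      f"({t.case_carrier_fraction:.2%})")
print(f"control carriers: {t.c}/{t.n_controls} "
      f"({t.control_carrier_fraction:.2%})")
print(f"odds ratio: {report.oddsratio:.2f} "
      f"(95% CI {report.ci_low:.2f}-{report.ci_high:.2f})")
print(f"one-tailed Fisher exact p: {report.p:.4f}")
print("\nAn odds ratio near 1.9 with an interval excluding 1 replicates "
      "the discovery-stage signal in an independent cohort; the "
      "one-tailed test asks specifically for carrier excess in cases.")
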