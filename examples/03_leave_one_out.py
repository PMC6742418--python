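"""Leave-one-out localization of the variants driving a gene association.

Plants three causal variants (odds ratio 6) in the first third of a
40-variant gene, scans 30-variant windows, then drops single variants
inside the implicated window and reports which ones move the p-value by
at least 35%.
"""

from mistloo.loo import loo_variant_scan, loo_window_scan
from mistloo.mist import fit_null_logistic
from mistloo.simdata import simulate_planted_region

region, cohort = simulate_planted_region(n_variants=40, n_causal=3, seed=3)
causal = set(region.causal)
nf = fit_null_logistic(cohort.y, cohort.X)

print(f"planted causal variant indices (0-based): {sorted(causal)}\n")
windows = loo_window_scan(region, cohort, null_fit=nf)
for w in windows:
    print(f"window {w.start:>2d}-{w.end:<2d}  p_full={w.p_full:.3g}  "
          f"p_drop={w.p_drop:.3g}  flagged={w.flagged}")

flagged = [w for w in windows if w.flagged]
results = loo_variant_scan(region, cohort, flagged, threshold=0.35,
                           null_fit=nf)
print("\nvariants with >= 35% p-value increase when dropped:")
for r in results:
    if r.flagged:
        mark = "CAUSAL" if r.index in causal else "false flag"
        print(f"  index {r.index:2d}  "
              f"pct_increase={r.pct_increase_display:.2f}  ({mark})")
print("\nA flagged variant is one whose removal weakens the region "
      "association; the 35% threshold was calibrated by ROC against "
      "known pathogenic variants.")
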