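# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## The region test

The per-gene test is a mixed-effects score test for a hierarchical
logistic model: variant effects `β = Zπ + b` with `b ~ (0, τ²I)`. The
burden component is a Rao score test of `π = 0` in `y ~ X + GZ`,
chi-square with `q = rank(GZ)` degrees of freedom after pruning
degenerate columns; the variance component tests `τ = 0` through
`S_τ = ‖Gᵀr‖²`, `r` the residuals of the π-model, whose null distribution
is the chi-square mixture `Σ λ_k χ²₁`, `λ_k` eigenvalues of `GᵀPG` with
`P = W − WM(MᵀWM)⁻¹MᵀW` and `M = [X, GZ]`. The two p-values are
asymptotically independent (the variance component is computed after
projecting out the burden directions) and are combined with Fisher's
method on four degrees of freedom. Annotations enter only through `Z` in
the burden; residual effects are unweighted.

**Annotation matrix.** `Z` defaults to intercept + CADD (z-scored within
the region, so the weighting is *relative* deleteriousness) + one-hot
indicators for frameshift, non-frameshift indel, nonsense and splicing,
with missense as the reference class. Constant or collinear columns are
pruned with a warning — a region of pure missense variants degrades
gracefully to intercept + CADD. Missing CADD values are imputed to the
region mean before scaling.

**Null model.** Logistic IRLS written in-package, converging on a score
norm ≤ 1e-8, with step-halving as a separation guard. Keeping the fit
in-package lets statsmodels' GLM score test act as a genuinely
independent oracle in the test suite.

**Chi-square mixture tail.** The exact tail is computed by numerical
inversion of the characteristic function (Imhof's integral, absolute
quadrature tolerance 1e-11); when the quadrature fails or returns a
non-positive value — which happens in the far tail, where the integral is
smaller than its error bound — the Liu-Tang-Zhang three-moment
approximation takes over, and the result records which path was used.
Eigenvalues below `1e-10 × λ_max` are treated as zero. All p-values are
floored at 1e-300.

**Missing genotypes** are imputed to the variant's non-missing mean at
test time (preserves allele frequency); they are never silently coerced
to zero in storage.

## Leave-one-out localization

Windows of 30 variants step by 20 through the gene's position-ordered
variant list; when the next full window would overrun the gene, the final
window is left-shifted to cover the last 30 variants, which guarantees an
overlap of at least 10 with its neighbour (a 44-variant gene gives
windows 1–30 and 15–44; 96 variants give five windows). A window is
implicated by any strict increase of the recomputed p over the full-gene
p. Within implicated windows, single variants are dropped against the
window-subset p by default (`scope="gene"` compares against the full-gene
p instead; both readings of the procedure are supported because the
sources describing it are ambiguous between them). The flag threshold is
a ≥35% relative p increase; a variant sitting in two implicated windows
is flagged if either evaluation crosses the threshold and reports its
maximum increase. Reports cap the displayed increase at 105%, mirroring
the ">105%" convention of published candidate tables; the uncapped value
stays available. Flagged variants with CADD in [0, 1] are disregarded as
unlikely to alter function. A gene is retained as case-driven only when
the carrier *frequency* of its flagged variants is strictly higher in
cases; ties classify as control-driven, i.e. conservatively excluded.

The 35% threshold itself is calibrated by ROC against a labeled set of
known pathogenic variants: thresholds 5%–105% in 5-point steps, choosing
the maximizer of Youden's J with ties broken toward the stricter
(larger) threshold. Sensitivity and specificity carry exact
Clopper-Pearson intervals; with only nine labeled positives the
sensitivity interval is necessarily wide (66%–100%).

## Filters and ancestry QC

Variant filters: consequence class not in {synonymous, other}; folded
minor-allele frequency in *controls* ≤ 1% with the boundary retained;
read depth ≥ 10 in at least one sample. A variant failing several rules
is counted under the first failing rule (class → MAF → depth). Genes with
fewer than 10 remaining variants are dropped — the region test is not
meaningful below that. Filters are idempotent.

Ancestry screening standardizes common variants (folded MAF ≥ 5%),
projects samples onto two principal components and flags any sample whose
per-axis distance to its nearest population centroid exceeds 10 SD
(a Euclidean rule is config-switchable). Cluster location and scale are
the per-axis median and 1.4826×MAD rather than mean and SD: a handful of
genuinely admixed samples inside a labeled cluster otherwise inflates the
cluster SD enough to mask themselves, which we observed directly on
synthetic three-population fixtures. Clusters come from provided labels,
or from k-means on the two PCs when labels are absent.

## Validation and design statistics

The validation stage counts unique carriers of qualifying nonsynonymous
variants per group and reports the odds ratio with a Wald 95% interval on
the log scale plus a one-tailed Fisher exact p for enrichment in cases
(the direction of the hypothesis being validated). Zero cells get the
Haldane-Anscombe +0.5 correction for the OR and interval, flagged in the
result; the exact p always uses raw counts. Benjamini-Hochberg q-values
accept a family size `m` larger than the number of supplied p-values,
treating the unobserved tests as large enough not to enter the step-up
minimum — the situation when only a published table truncated at p ≤ 0.05
is available. The two-proportion sample-size routine uses the
pooled-variance normal approximation with unequal allocation and a
one-sided level by default; its Monte-Carlo companion shows the actual
pooled Z test is anti-conservative relative to that approximation when
the comparison proportion is ~0.1% (simulated power ≈0.91 at the size
solving for 0.80), so the returned size is safe rather than sharp.

## The synthetic-data generator

`simulate_cohort` draws per-gene variant sets with log-uniform MAF on
[1e-4, 0.01] (the rare spectrum the filters target), consequence classes
at panel-realistic proportions (80% missense), CADD uniform on [0, 15]
for benign and [15, 40] for causal variants (only the ordering matters to
any test), Hardy-Weinberg genotypes, negative-binomial read depths
(mean 60), and case status from a logistic model with baseline prevalence
≈1% and planted causal effects (default log OR = ln 5). Case-control
ascertainment is by rejection sampling from the population model;
non-causal genes are simulated after sampling, which is distributionally
exact because they are independent of phenotype, and keeps the generator
fast. Default cohort 398 cases / 987 controls, matching a two-series
discovery design. All output is a pure function of the config, seed
included.

Planted-truth fixtures used for power and recovery checks draw their
*causal* variants' MAF from 0.003–0.01: a causal variant with a single
expected carrier is undetectable by any drop-one analysis, so placing
planted effects in the detectable-rare band is what makes recovery a test
of the method rather than of luck. Benign variants keep the full
spectrum.

`simulate_common_variants` adds Balding-Nichols-style population
structure (per-cluster allele-frequency drift of magnitude `fst`) for the
PCA screen. The generator does **not** model linkage disequilibrium,
sequencing error, relatedness, covariate confounding or fine-scale
admixture; passing tests therefore demonstrate the statistical machinery
on idealized genotypes, not robustness to those real-data features.

`make_worked_example` packages deterministic worked-example structures —
a 96-variant calibration gene with nine labeled truncating/splicing
pathogenic variants, 45- and 44-variant genes for the window layouts, a
418-gene size table of which 183 fall below the 10-variant floor, a
percent-increase table whose 35%-threshold confusion is 9/9 and 76/86,
and a 41/532 vs 32/753 validation table — so every downstream stage can
be exercised without external data.

## Validation designs behind the test suite

- The burden component with `Z = 1` is checked against statsmodels' GLM
  score test to 1e-8 across 50 seeded datasets.
- The variance-component tail is compared with a 2000-permutation null on
  20-variant regions at n = 800 with MAF 5–20%. The size matters: the
  asymptotic mixture and the permutation null differ systematically in
  the distribution's bulk for sparse regions at small n (binary residuals
  have non-zero excess kurtosis the Gaussian quadratic-form theory
  ignores), a gap that can exceed pure Monte-Carlo noise at n = 300. The
  implementation was additionally verified against a parametric bootstrap
  of the fitted model, which targets exactly the hypothesis tested.
- Type-I error is measured over 1000 null 20-variant genes at n = 400 on
  the generator's sparse spectrum and must land in the exact central 99%
  binomial interval around 0.05; p-value *uniformity* (Kolmogorov-
  Smirnov) is asserted at the discovery-cohort scale (n = 1385), where
  the asymptotics hold across the whole distribution.
- Leave-one-out recovery plants three causal variants (OR 6) among 40 and
  requires every planted variant flagged with a pooled false-flag rate
  ≤10% across five seeded fixtures (pooling because 27 non-causal
  variants per fixture quantize a per-fixture rate too coarsely).

## Known limitations

- The variance-component null is asymptotic; for genes whose variants are
  all singletons/doubletons at a few hundred samples, mid-range p-values
  can deviate from uniform even though the 5% tail stays calibrated. A
  small-sample moment adjustment is a known remedy but is deliberately
  out of scope, matching the published structure of the test.
- Fisher's combination assumes independence of the two component
  p-values, which holds asymptotically but is another small-sample
  approximation.
- The leave-one-out analysis drops variants marginally; it cannot
  disentangle variants whose carriers overlap (no haplotype or
  conditional analysis).
- One-sided validation testing presumes the discovery direction
  (enrichment in cases); protective effects require the two-sided option.
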