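# Methods

This note documents the statistical model behind `tiermeta`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Differential expression (per study)

Each study is a two-group (case vs control) design with no covariates —
the design every emulated study shares. Preprocessing drops any gene row
containing a missing value (determinism and simplicity were preferred over
per-cell imputation, which would entangle downstream p-values with an
imputation model) and applies `log2(x+1)` only when the matrix maximum
exceeds 50. That threshold separates raw microarray intensities (typically
hundreds to tens of thousands) from already-logged data (log2 scale rarely
exceeds ~16) with a wide safety margin in both directions; negative raw
values are clamped to zero first.

The moderated t assumes gene-wise variances follow a scaled inverse
chi-square prior, `s² | σ² ~ σ²·χ²(d_g)/d_g` with `σ² ~ s₀²·d₀/χ²(d₀)`.
Hyperparameters are estimated by moment matching on `e = ln s²`:

* `var(e) = trigamma(d_g/2) + trigamma(d₀/2)` is inverted for `d₀` with a
  monotone Newton iteration on the trigamma function (tolerance 1e-8,
  ≤ 50 iterations, with the asymptotic branches `1/√y` for y > 1e7 and
  `1/y` for y < 1e-6);
* `ln s₀² = mean(e) − digamma(d_g/2) + ln(d_g/2) + digamma(d₀/2) − ln(d₀/2)`.

When the observed `var(e)` does not exceed the pure sampling variance
`trigamma(d_g/2)` there is no evidence of variance heterogeneity and the
`d₀ = ∞` limit is returned (every posterior variance pinned to `s₀²`,
normal-theory p-values). `d₀ = 0` recovers the ordinary pooled t exactly
(used as an internal consistency check against `scipy.stats.ttest_ind`).
Zero sample variances are replaced by the smallest positive variance
observed before taking logs; p-values are clamped to ≥ 1e-300 so downstream
log-space combination stays finite.

## Fisher combination and corrections

Fisher's statistic `−2 Σ ln pᵢ` is referred to χ²(2k). Genes absent from
some studies (platform dropout) are combined over the studies that measured
them — `k` varies per gene — rather than dropped; discarding them would
bias the disease gene list toward genes on every platform. Independence is
checked, not assumed: all study-pair Pearson correlations of p-values are
reported, and pairs with |r| ≥ 0.30 and test p < 0.05 are flagged with a
warning. Flags never abort the run — on planted synthetic data the shared
true signal itself induces correlation, exactly as shared biology would.

BH and BY are implemented as step-up *adjusted p-values* (delegated to
`statsmodels.stats.multitest`) so one alpha applies to every correction.
Note an ordering subtlety: Bonferroni and BH, and BY and BH, are ordered
elementwise (Bonferroni ≥ BH, BY = min(1, BH·c(m)) ≥ BH ≥ raw), but
Bonferroni and BY are *not* — at top ranks BY's harmonic factor
`c(m) = Σ 1/i` makes it the stricter correction (`c(m)·m·p > m·p`).

## Enrichment

Over-representation uses the upper hypergeometric tail P(X ≥ k) — strictly
"k or more" — via `scipy.stats.hypergeom`. The universe is the set of genes
that received a combined p-value in the disease (what was testable), not
the collection's gene union; conditioning on an inflated universe would
anti-conservatively shrink every tail. Pathway sizes for the 10–300 filter
are measured within the collection (mirroring how pathway databases are
pruned), while the per-test `K` is universe-intersected. A pathway disjoint
from the universe is reported with K = 0 and p = 1 rather than dropped, so
the cross-disease table stays rectangular.

## Cross-disease combination

Diseases where a pathway has no overlap carry p = 1. The default
`include_ones` policy keeps them in the combination (full df = 2·D; a p of
1 contributes 0 to the statistic), which matches printing a '1' in the
per-disease columns and combining across all of them; `drop_ones` excludes
them (df = 2·#overlapping). Both give the same statistic and differ only in
df, so both are provided. The Bonferroni family is the set of pathways
actually tested in the run (post size-filter), recomputed per collection.
Final ranking sorts by combined p with ties broken by pathway name for
determinism.

## Permutation-null calibration

Null runs randomly split the unlabeled healthy cohort into balanced halves
(⌊n/2⌋ vs rest — "random assignment" is under-determined; a balanced split
maximizes power symmetry across runs), fit the moderated t, select genes at
*uncorrected* p < 0.05 (FDR-corrected selection on a true null retains
essentially nothing, making every enrichment p exactly 1 and the prior
degenerate), and score all pathways hypergeometrically. The prior `q` is
the significant-run fraction out of R = 100, clamped to
[0.5/R, 1 − 0.5/R]: a pathway never significant in R runs has an
*estimated* q of 0, but posterior odds require q ∈ (0,1), and half a count
is the usual continuity correction.

Minimum Bayes factors follow the p-value bound (−e·p·ln p for p < 1/e,
else 1; this is the exact minimum over the beta-family of alternatives,
verified in tests against direct numeric minimization) and the χ² bound
((v/x)^(−v/2)·e^(−(x−v)/2) for x > v, evaluated in log space). The
combined-case BF uses the tier-3 statistic and its recorded df (hence
policy-dependent), and the same per-pathway q — no separate combined prior
is defined. The formulas treat q as the prior probability of the null for
that pathway even though it is estimated as a chance-significance rate;
the two coincide only loosely, and the resulting posterior should be read
as the calibration bound it is, not as a full Bayesian posterior.
"Average null distribution" means the per-pathway arithmetic mean across
runs (what the QQ diagnostic consumes); a pooled empirical distribution is
available as an option.

## QQ diagnostics

Hazen plotting positions (i − 0.5)/n throughout. Two scales are emitted:
sorted −log10 p against uniform order-statistic quantiles, and the
null-combined statistic −2(ln p_disease + ln p̄_null) against χ²(4)
quantiles, summarized by the inflation ratio median(observed)/
median(expected).

A calibration caveat, measured and deliberate: under a global null with
i.i.d. synthetic data the inflation ratio is systematically *below* 1
(≈ 0.41–0.58 across seeds). Two effects compound. First, p̄_null is a mean
of R = 100 p-values and concentrates near E[p] instead of varying like a
uniform draw, so its term contributes a near-constant ≈ −2 ln 0.6 rather
than a χ²(2) variate; even with perfectly uniform inputs the attainable
median ratio is ≈ 0.83, not 1. Second, at synthetic overlap scales
(K·n/N ≈ 1) the hypergeometric tail is discrete and conservative
(E[p] ≈ 0.65). Real cohorts, whose gene-coexpression structure spreads
per-pathway null means over (0,1), can look better calibrated here than
this i.i.d. simulation — a deviation *below* the diagonal in this
diagnostic indicates conservatism, not error. The enrichment direction of
the diagnostic (planted signal lifting top-rank statistics far above the
χ²(4) 99.9% quantile) is unaffected.

## Classification harness

Classifiers are fixed, plain variants (linear-kernel SVM with C = 1, kNN
with k = 5, LDA, Gaussian naive Bayes) under stratified 3-fold CV with
features standardized on training folds only. Studies are classified
separately and averaged — pooling raw measurements across platforms is
exactly what the p-value-only design avoids. FDR-method selection scores
each correction's gene set across all studies and classifiers and breaks
ties toward the more conservative correction (fewer features at equal
accuracy); an empty gene set scores as the majority-class baseline.
Pathway-power comparisons draw 100 random gene sets per study, matched in
size to the pathway-overlap feature set and disjoint from the pathway
union, from that study's measured genes.

## Synthetic data: what it emulates, and what it does not

Expression is generated directly on the log-intensity scale — per-gene
baselines μ_g ~ Normal(8, 1.5²) shared across all studies, i.i.d.
Normal(μ_g, σ²) samples with σ = 1 — so the preprocessing log rule is a
deliberate no-op on synthetic data and the moderated-t normality
assumptions hold exactly. Planted pathways add δ·σ to case samples of
affected diseases; per-disease background DE genes (2% of non-planted
genes by default, shifts of random sign with magnitude Uniform(0.5, 1.5)·σ)
are kept disjoint from planted pathways so recovery tests are unambiguous.
Platform differences are emulated by dropping whole gene rows per study
(10% by default); cell-level missingness is a separate knob (`na_fraction`,
0 by default). The default scenario — 8 diseases × 3 studies × 20 samples
per group, 2000 genes, 40 pathways of 10–30 genes, one pathway planted in
6 diseases at δ = 1 — keeps every disease above the 30-sample floor real
cohorts were required to meet; the healthy null cohort defaults to 109
samples. Not emulated: batch effects, probe saturation, platform-specific
intensity distributions, and gene–gene correlation (so passing tests
demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to real-microarray artifacts — in particular
the null-QQ conservatism above).

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use: 20 seeded replicates for
planted recovery, 50 for the all-null family-wise check, 20 (script;
50 in tests) for QQ calibration, 100 permutation-null runs per cohort, and
100 random gene sets per classification comparison. Every random draw
flows from an explicit integer seed through `numpy`'s `SeedSequence`
substreams (simulation, null runs, CV splits, and random gene draws each
get their own stream), so whole-pipeline runs are bit-reproducible and
individual stages can be re-run in isolation.
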