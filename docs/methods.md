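# Methods

## Data model

The unit of analysis is a published case-control study of a biallelic
variant, stored as genotype count triples (CC, CT, TT) for cases and
controls plus the reported sample sizes, a region tag, and (optionally) the
HWE p-value the original table printed.  Genotype counts and reported n are
kept independently: four rows of the bundled rs966221 table have genotype
sums that disagree with the reported sample sizes (Shao 2013 cases 294 vs
394; Cheng 2011 controls 231 vs 258; Wang 2017 controls 616 vs 618; Sun 2009
cases 648 vs 649).  The genotype counts are the source of truth for every
statistic — pooling the printed genotype rows reproduces the published
pooled estimates exactly, so those rows are what was analysed — and the
mismatches are surfaced as validation warnings, never "corrected", since the
cause (typos vs partial genotyping) cannot be recovered from the table.

Region tags are free text with a documented canonical vocabulary (the seven
Chinese geographic regions plus "Multi").  The Xue 2009 cohort spans
Northwest, Southwest, and North China and is tagged "Multi"; subgroup
analysis excludes it from every region.

## Per-study statistics

* **Allelic (additive) model.** Each subject contributes two alleles:
  C = 2·CC + CT, T = 2·TT + CT per arm, giving a 2×2 allele table.  No
  genotypic (dominant/recessive) contrasts are implemented.
* **Odds ratio.** Cross-product estimate with the Woolf log-scale variance
  (sum of reciprocal cells).  The 95% CI uses the fixed critical value
  z = 1.96 rather than a re-derived quantile; this matches the display
  precision of published tables.  A zero cell triggers the Haldane–Anscombe
  +0.5 correction of all four cells (none is needed for the bundled table;
  it matters for small simulated cohorts).  A table with an empty margin has
  no OR and raises an error rather than returning an arbitrary value.
* **HWE screen.** The plain (uncorrected) 1-df chi-squared goodness-of-fit
  test at the estimated allele frequency, applied to the control arm, with
  screening threshold p < 0.001 (configurable).  Monomorphic input raises an
  error: with one allele there is nothing to test.  Published HWE p-values
  are carried as metadata only; some of them (e.g. Jiang 2018: printed 0.228
  vs chi-squared 0.14) are consistent with an exact HWE test rather than the
  chi-squared, so recomputed and printed values are not expected to agree
  digit-for-digit.

## Pooling

Fixed-effect pooling is inverse-variance on log-ORs (not Mantel–Haenszel;
both reproduce the bundled subgroup results, but inverse-variance composes
directly with the random-effects weights).  Random effects use the
DerSimonian–Laird method-of-moments τ², truncated at zero, with weights
1/(v_i + τ²).  I² is truncated at zero when Q < k−1.  Model selection is the
screening rule *random iff p(Q) < 0.1 and I² > 50%* (both thresholds
configurable); both conditions are strict inequalities.  The pooled log-OR
is tested against zero with a normal Z test.  No Hartung–Knapp adjustment,
prediction intervals, REML/Paule–Mandel τ², or meta-regression: the scope is
the classic two-model toolkit.

A single study "pools" to itself under the fixed model; heterogeneity and
random-effects pooling require k ≥ 2, leave-one-out and Egger k ≥ 3, all
enforced with explicit errors.

## Subgroups, sensitivity, publication bias

Subgroups are formed by region tag in first-appearance order; groups with
fewer than `min_k = 2` studies are marked insufficient instead of pooled
(two-study subgroups are pooled — the bundled South and Central regions —
while a singleton region is not).  Leave-one-out re-pools each reduced set
with heterogeneity and model selection re-run per set (`model_rule="auto"`),
since a single influential study can flip the heterogeneity verdict.

Egger's test is the classic unweighted OLS of the standardized effect
y_i/se_i on the precision 1/se_i, intercept tested two-sided on t with k−2
df.  Weighted variants of this regression move the p-value in the second
decimal; results should be read at that resolution.  A design in which all
studies share one standard error makes the precision term constant and the
regression unidentifiable; this raises an error.  Funnel coordinates are
stored as (log-OR, se); the OR axis is a rendering choice.

## Display conventions

Internally everything is natural-log and full precision.  Displayed ORs and
CI bounds are rounded half-even to 2 decimals, I² to 1 decimal.  Published
CI bounds are not all consistent with a single rounding rule — the bundled
table's Northeast bounds (printed 1.13–1.44) recompute to 1.1352–1.4464,
and the Central upper bound (printed 2.60) to 2.61, i.e. the source display
appears truncated in places — so the last printed digit of a CI bound is
treated as ±1 unit rather than exact.

## Synthetic cohorts

The generator mirrors the structure the analysis assumes.  Per study:
control C-allele frequency p₀ ~ Uniform(p0_range); study-level true log-OR
θ_i = μ + N(0, τ²); case allele frequency from the allelic odds model
p₁ = e^θ p₀/(1−p₀) / (1 + e^θ p₀/(1−p₀)); genotypes trinomial with HWE
proportions (p², 2pq, q²) in each arm at its own allele frequency.  Defaults
mirror the bundled table's shape: k = 14 studies, 100–900 subjects per arm,
p₀ ∈ [0.2, 0.5] (the band the bundled control frequencies occupy), true OR
1.15 and τ² = 0.09 (the overall DL estimates from the bundled table).
Giving cases HWE proportions at their shifted allele frequency is exactly
consistent with the allele-level analysis but is an approximation to any
particular genotype-penetrance model; the generator encodes no linkage
disequilibrium, covariates, or population stratification, so passing
recovery tests validate the estimators under the model's own assumptions,
not robustness to real-data artefacts.  Arms that come out monomorphic are
redrawn so every record is analysable (vanishingly rare at the default
sizes).  All randomness flows from one integer seed through numpy's PCG64;
`run_recovery` spawns per-replicate seeds from it, so summaries are exactly
reproducible.

## Problem sizes used in validation

The operating-characteristic checks use 1000 replicates for null
size/coverage (k = 10, 500 per arm; binomial MC error ≈ 0.7 points on a 5%
rate), 500 for bias under a real effect, and 200–300 per point of the τ²
grid — enough for the monotonicity and band checks they support while
keeping the whole suite fast.

## Known limitations

* Aggregate counts only; no individual-level data, VCF/PLINK input, or
  covariate adjustment.
* The two-model (fixed/DL) toolkit with a hard selection rule, as used in
  the applied literature it targets; modern practice often prefers REML τ²
  with Hartung–Knapp intervals, which are out of scope here.
* The Egger p-value is formulation-dependent at the second decimal (see
  above).
* The HWE screen tests the control arm only and is a goodness-of-fit screen,
  not an exact test.
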