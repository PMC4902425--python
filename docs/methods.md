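# Methods

## The two-stage design

`metamr` implements a two-stage analysis for a single biallelic variant
used as an instrumental variable:

1. **Gene–disease stage.** K case–control studies each report genotype
   counts (CC/CT/TT in cases and controls). Per study, the 3×2 table is
   collapsed into a 2×2 under a genetic-model contrast and summarized as
   a log odds ratio θ̂ᵢ with Woolf standard error
   √(1/a + 1/b + 1/c + 1/d). The θ̂ᵢ are pooled by inverse-variance
   weighting, fixed-effect and DerSimonian–Laird random-effects.
2. **Mendelian-randomization stage.** The pooled per-allele (allele
   model) log-OR is divided by the per-allele effect of the variant on
   the exposure (here: SD units of natural-log plasma total
   homocysteine per T allele, taken from external GWAS summary data),
   giving the Wald-ratio causal log-OR of disease per SD of exposure.

The MR step assumes the instrument is (i) associated with the exposure,
(ii) independent of confounders of the exposure–disease relation, and
(iii) affects disease only through the exposure (no pleiotropy). None
of these is testable with a single variant; the package computes the
estimator, it does not validate the assumptions.

## Pooling and heterogeneity

Fixed-effect weights are wᵢ = 1/seᵢ²; the pooled estimate is
Σwᵢθ̂ᵢ/Σwᵢ with SE 1/√Σwᵢ. Cochran's Q = Σwᵢ(θ̂ᵢ − θ̂_F)² is referred
to χ²(k−1); I² = max(0, (Q − (k−1))/Q)·100. The DerSimonian–Laird
moment estimator is

    τ̂² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)),

and random-effects weights are wᵢ* = 1/(seᵢ² + τ̂²). When Q ≤ k−1 the
truncation makes the random-effects result identical to the fixed one;
k = 1 returns Q = 0, q_p = 1, I² = 0 by convention.

**Model selection.** The random-effects result is labeled primary when
q_p < 0.1 **or** I² > 50%, the fixed-effect result otherwise. Both are
always computed and reported, so the screening rule only chooses the
headline row.

## Per-study computations

- **Contrasts**: allele (T vs C, alleles counted as 2·TT + CT, treating
  a person's two alleles as independent observations), homozygous
  (TT vs CC), heterozygous (CT vs CC), dominant (TT+CT vs CC),
  recessive (TT vs CT+CC). The homozygous/heterozygous contrasts are
  pure 2×2 tables on the two named genotypes; excluded genotypes drop
  out of both margins.
- **Continuity correction**: 0.5 is added to all four cells only when
  at least one cell is zero (Haldane–Anscombe). A table with an empty
  row or column has no estimable OR; the study is dropped from that
  model's pooling with a logged warning.
- **HWE check**: Pearson χ² of the three control genotype cells against
  p², 2pq, q² with the allele frequency estimated from the same data
  (1 df, asymptotic). Monomorphic control arms return p = 1 by
  convention. Studies failing at α = 0.05 are flagged and removed in
  the HWE-exclusion sensitivity analysis; the exact/mid-p variants are
  deliberately out of scope.

## Publication-bias diagnostics

**Egger's test** regresses the standardized effect θ̂ᵢ/seᵢ on precision
1/seᵢ by OLS; the intercept's t statistic (k−2 df, two-sided) tests
funnel asymmetry. A zero-residual fit (e.g. exactly constant effects)
is degenerate and reported with p = 1 and a warning.

**Begg's test** rank-correlates the variance-stabilized deviates
uᵢ = (θ̂ᵢ − θ̂_F)/√(seᵢ² − 1/Σw) with the variances seᵢ², using
Kendall's S with the standard tied-group variance adjustment and a
continuity correction of 1 on |S|.

Both tests are labeled at α = 0.05. P-values near that boundary should
not be over-read: with k in the twenties these tests have limited and
asymmetric power, and a marginal Egger p alongside a null Begg p is a
common, ambiguous outcome that the report presents without resolving.

## The Wald ratio and its standard error

With gene–disease log-OR θ̂ (SE se_θ) and gene–exposure effect β̂
(SE se_β), the causal estimate is γ̂ = θ̂/β̂. Two delta-method SEs:

- `simplified` (default): se_θ/|β̂| — treats β̂ as a known constant,
  appropriate when it comes from a GWAS far larger than the outcome
  sample, and the convention used for the headline numbers here;
- `full`: √(se_θ²/β̂² + θ̂²·se_β²/β̂⁴) — first-order propagation of
  both uncertainties; recommended whenever se_β is available.

`se_from_ci` reconstructs se_θ = (ln hi − ln lo)/(2·1.96) from a
published 95% CI. For the package's worked example (per-allele OR 1.16,
CI 1.06–1.27, β = 0.158 SD/allele) the simplified delta method gives
OR 2.56 per SD with 95% CI 1.44–4.53; any interval much narrower than
that cannot arise from delta-method propagation of those three inputs.
|β| < 0.01 SD/allele flags the result as weak-instrument.

All intervals use the normal 1.96 quantile and all p-values are
two-sided.

## Synthetic-data generator

`simulate_studies` emulates a literature-extracted collection: per
study it draws a control T-allele frequency q ~ U(maf_range), a study
effect δᵢ = true_log_or + N(0, τ²), control genotype probabilities at
Hardy–Weinberg proportions, case probabilities by multiplicative
per-allele odds weighting w(g) ∝ P_ctrl(g)·e^{δᵢ·g} (g = T-allele
dose; under HWE controls this makes the allele-contrast OR exactly
e^{δᵢ}), and multinomial counts at per-arm sizes drawn from the
configured ranges. Designated HWE-violating studies distort control
frequencies with an inbreeding coefficient F (heterozygote deficit).
Optional small-study bias censors imprecise studies (SE above
`small_study_se`) whose estimate falls below the true mean, redrawing
until acceptance.

Defaults describe a 27-study meta-analysis of MTHFR C677T and gastric
cancer: per-arm sizes 100–400 cases / 150–500 controls (matching
aggregate totals of ~6300 cases and ~8300 controls over 27 studies),
q ∈ (0.2, 0.5), true allele OR 1.16, τ = 0.1, β = 0.158 SD/allele
treated as exact (se_β = 0). `paper27_config()` adds 7/27 HWE
violators with F = 0.2. Each study gets its own seeded substream
(root seed + study index), so enlarging k never reshuffles earlier
studies, and the gene–exposure draw uses a reserved substream.

**What the generator does not emulate**: genotyping error, ethnicity-
dependent allele frequencies or effect sizes, correlated studies
(overlapping populations), covariate-adjusted ORs, and selective
outcome reporting beyond the simple censoring rule. Passing calibration
tests therefore demonstrate correctness of the estimators under the
stated sampling model, not robustness to those real-data features.

## Simulation sizes and known limitations

Calibration checks in the test suite use 500–2000 replicates: 2000 for
CI coverage and bias-test null rates (Monte-Carlo SE ≈ 0.5 points),
500 for τ² recovery, fixture coverage and end-to-end truth recovery —
enough replication for the stated bands while keeping the suite a
routine run.

- **DL interval undercoverage.** With k = 27 and between-study variance
  comparable to within-study variance, DerSimonian–Laird z-intervals
  cover a true heterogeneous mean ~93% of the time rather than 95%, and
  the threshold-selected ("primary") interval is worse (~92%) because
  the screening rule keeps the fixed model precisely in replicates
  where Q under-detects heterogeneity. This is a property of the
  estimator family (reproduced here with idealized normal effects), so
  coverage acceptance is assessed on the random-effects interval, which
  matches the τ > 0 generating truth; Knapp–Hartung-type corrections
  are out of scope.
- The allele model's independence assumption ignores within-person
  allele correlation; under HWE this is the standard simplification.
- The Wald ratio is consistent only for a valid instrument; with a
  noisy β̂ the plain ratio is slightly biased (no Fieller or
  bootstrap interval is provided).
- Subgroup pooling re-runs the full pipeline per stratum and inherits
  all small-k caveats within strata.
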