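# Methods

## Model and estimators

The package implements summary-statistic two-sample Mendelian randomization.
Each instrument j contributes an exposure association β̂_xj (SD units per
effect-allele copy, from a quantitative-trait GWAS) and an outcome
association β̂_yj (log-odds per copy, from a case-control GWAS).  Under the
instrumental-variable assumptions (relevance, independence from confounders,
exclusion restriction), the ratio θ_j = β_yj/β_xj identifies the causal
log-odds of the outcome per SD of exposure, and a common θ across
instruments justifies fixed-effects pooling.

**Wald ratio.** θ̂_j = β̂_yj/β̂_xj.  Two SE approximations are offered:

- *first order* (default): se = se_yj/|β̂_xj|, which conditions on the
  exposure estimate.  This is the convention that matches the published
  intervals reproduced by the packaged example, and is accurate when the
  instrument is strong (|β̂_x|/se_x large).
- *second order*: se = √(se_y²/β_x² + β_y²·se_x²/β_x⁴), the delta-method
  expansion that also propagates exposure-side noise.  The test suite checks
  it against a 10⁶-draw parametric bootstrap of the ratio.

A zero exposure effect raises a weak-instrument error rather than returning
an infinite ratio.

**IVW pooling.** Fixed effects only: θ̂ = Σwθ̂_j/Σw with w_j = se_j⁻²,
se(θ̂) = (Σw)^(-1/2), two-sided normal p-values throughout (summary-statistic
asymptotics; no small-sample t correction).  Heterogeneity is reported, not
acted on: Cochran's Q on k−1 df, I² = max(0, (Q−df)/Q) (Q below its df
truncates I² to zero), and a warning when Q is significant at 5%.  No
random-effects fallback is applied automatically.

**I² confidence interval.** The test-based (ln H) method: H = √(Q/df),
se(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2df−1)) when Q > k and
√(1/(2(k−2))·(1 − 1/(3(k−2)²))) otherwise, interval exp(ln H ± 1.96·se)
floored at H = 1 and mapped through I² = (H²−1)/H².  This method was chosen
over profiling the non-central chi-square because it is the one that yields
the characteristically wide small-k intervals (0–90% at k = 3 with Q ≈ 0)
seen in published fixed-effects MR reports, including the packaged example.
Below k = 3 the interval is reported as the degenerate (0, 1).  The I² CI is
descriptive only; no decision in the pipeline depends on it.

## Scale conversions and harmonization

Published case-control results often arrive as OR with a 95% CI.  The
conversion ln-transforms the point estimate and reconstructs
se = (ln hi − ln lo)/(2z) with the exact quantile z = 1.959964.  A CI
printed to 2 d.p. propagates ~1% relative error into the SE — the reason
recomputed results can differ from originals in the last printed digit.
When a table prints an effect and p-value but no SE, se = |β|/Φ⁻¹(1−p/2).

Harmonization aligns each outcome record to the exposure's effect allele:
identical pairs pass through, swapped pairs sign-flip, opposite-strand pairs
are complemented (with a sign flip if also swapped).  Palindromic SNPs (A/T,
G/C) cannot be strand-resolved from alleles; their strand is inferred from
allele-frequency concordance, except within a window of ±0.08 around
EAF 0.5 (configurable) where they are dropped.  Frequencies are never
guessed: a palindromic SNP without EAF in both studies raises a
frequency-required error.  Finally each pair is oriented so the exposure
beta is non-negative (instruments point to the exposure-increasing allele).
Harmonization is idempotent, and the Wald ratio is invariant to re-expressing
either record for its other allele (property-tested).

## Instrument strength and power

R² per SNP is 2p(1−p)β² for a standardized trait, summed over independent
instruments.  On the packaged instrument table this gives 0.062; the source
publication quotes 6.8% from the original cohort (whose R² definition is not
printed).  Both numbers are surfaced and neither is asserted to be the
other; the power summary uses the table-derived value.

Binary-outcome power uses the non-centrality approximation
power = Φ(√(N·R²·K(1−K))·|ln OR| − z₁₋α/₂), with N the outcome GWAS size and
K its case fraction.  Several variants of this calculation circulate; this
symmetric-variance form is stated explicitly because it is (a) the one
consistent with the published replication-design figure of 99%, and (b)
internally consistent with the synthetic-data generator's noise model, so
analytic power and empirical rejection rates can be compared directly (the
suite requires agreement within 2 percentage points at 2,000 replicates).
`min_detectable_or` inverts the formula by bracketed root-finding on ln OR.

## Colocalization

Wakefield's approximate Bayes factor per SNP and trait:
log ABF = ½[log(1−r) + r·z²], r = W/(W+V), z = β̂/se, V = se², W = prior
effect variance.  Default prior SDs: 0.15 (quantitative), 0.2 (binary).
Hypothesis likelihoods are configuration sums — H1/H2 over single SNPs,
H3 over ordered distinct pairs, H4 over the diagonal — weighted by priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ per configuration, normalized to PP0–PP4.  All
accumulation is in log space (log-sum-exp); region-level sums overflow in
linear space at realistic z-scores.  H3 is obtained by subtracting the
diagonal from the full cross-product in log space; when a single SNP carries
essentially all evidence for both traits the cancellation is re-done as an
explicit off-diagonal sum to avoid catastrophic loss of precision.  A
one-SNP region has PP3 = 0 structurally.

The confounding-by-LD screen makes the usual visual inspection explicit: an
instrument is flagged when PP3 > PP4 (distinct causal variants more probable
than a shared one), with a configurable PP4 threshold above which shared
evidence always clears the instrument (at the default 0.5 the rule reduces
to the bare comparison, since posteriors sum to one).

## Phenome-wide scan

One IVW MR per catalogued outcome; family-wise error across the scan is
controlled by Bonferroni α/m.  m defaults to the catalogue size — an outcome
skipped for lack of instrument overlap still counts (conservative, and the
convention behind dividing by the number of outcomes attempted);
`denominator="tested"` switches to successful fits.  Skipped outcomes are
reported with reasons, never silently dropped, and sort after fitted rows.

## Synthetic-data generator

The generator emulates published summary statistics directly, not genotypes:

- exposure: β̂_x ~ N(β_x, se_x²), se_x = 1/√(2p(1−p)·n_exposure) — the
  standard error of a per-allele regression slope on a standardized trait;
- outcome: β̂_y ~ N(θβ_x + a, se_y²), se_y = 1/√(2p(1−p)·N·K(1−K)), i.e. the
  same effective-sample-size approximation as the power formula;
- pleiotropy a ~ N(μ, σ²) enters the outcome equation only — the violation
  the single-instrument sensitivity analysis probes (directional μ ≠ 0
  biases the pooled estimate by ≈ μ/mean(β_x); balanced σ > 0 inflates
  heterogeneity).

Defaults are the discovery design of the packaged example: three instruments
with SD effects (0.243, 0.312, 0.267) at minor-allele frequencies
(0.36, 0.05, 0.24) (true R² = 0.0625), exposure n = 3,636, outcome
12,882/21,770 cases/controls, true θ = ln 1.2.  Allele pairs are drawn per
SNP (palindromic with configurable probability), and outcome records are
emitted with randomly swapped allele labels so harmonization is exercised on
realistic input.  One seeded `numpy` Generator per call; identical configs
are byte-identical on disk.

Coloc regions: z-scores per trait are MVN with mean √n·R[:,c]·b (causal SNP
c, standardized effect b) and covariance R, where R is AR(1)-style LD,
R_ij = ρ^|i−j| (positive definite for 0 ≤ ρ < 1); β = z/√n, se = 1/√n.
Causal configurations: shared, distinct, trait1-only, null; a one-SNP
"distinct" region is rejected as structurally impossible.

What the generator does **not** emulate: LD between instruments (instruments
are independent by construction), allele-frequency mismatch between cohorts,
population stratification, sample overlap between exposure and outcome
GWAS, winner's-curse selection of instruments, and case-control ascertainment
beyond the effective-N approximation.  Passing calibration tests therefore
demonstrates internal statistical correctness of the estimators under the
stated sampling model, not robustness to those real-data complications.

## Numerical choices

- Exact normal quantile 1.959964 for 95% intervals (never 1.96).
- p-values floored at the smallest positive normal double so the "p in
  (0,1]" invariant survives extreme z.
- Q < df truncates I² at 0; k = 1 pools to the input with Q = 0.
- OR/CI display rounding 2 d.p., p to 2 s.f.; full precision in TSV/JSON.
- Root-finding: Brent on ln OR with bracket doubling, tolerance 10⁻¹².

## Test design and problem sizes

Deterministic results (the packaged example, conversions, thresholds) are
checked to the printed precision of their sources with explicit allowance
for CI-rounding of inputs (±0.01 on pooled OR/CI after 2-d.p. rounding,
±0.02 on the single-instrument OR, order-of-magnitude on the pooled p).
Stochastic calibration uses seeded replicate sets chosen to keep Monte-Carlo
error well inside the asserted bands: 2,000 replicates for CI coverage
(95% ± 2%) and type-I error (5% ± 1%), 2,000 for power-vs-simulation
agreement (±2 points), 500 × 50 outcomes for phenome-wide family-wise error
(≤ α plus two binomial SDs), 1,000 random instrument sets against the
weighted-least-squares oracle (10⁻¹⁰), and exhaustive enumeration oracles
for coloc posteriors on all regions up to six SNPs (10⁻¹⁰).

## Known limitations

- Only the ratio/IVW estimator family is provided — no MR-Egger, weighted
  median/mode, or correlated-instrument generalized IVW — so directional
  pleiotropy must be probed by design (cis instruments, sensitivity
  re-analysis, leave-one-out) rather than estimated.
- The coloc model assumes at most one causal variant per trait per region;
  allelic heterogeneity is outside its hypothesis space.
- Power and generator share the N·K(1−K) effective-size approximation;
  both are first-order in the rare-disease/log-odds linearization.
- No liftover, VCF parsing, LD-proxy lookup, or remote catalogue queries;
  inputs are local rsID-keyed tables.
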