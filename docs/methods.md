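# Methods

## Model

Penetrance of a risk variant is the posterior probability of disease given
carrier status,

    P(D|G) = P(G|D)·P(D) / (P(G|D)·P(D) + P(G|D̄)·(1 − P(D))),

with P(G|D) and P(G|D̄) estimated by the observed carrier proportions in
cases and controls and P(D) the lifetime morbid risk of the disease supplied
by the user (0.7% is the conventional figure for schizophrenia). The formula
assumes cases and controls are sampled from the same population the baseline
risk describes, and that carrier status is ascertained identically in both
arms. Frequencies are carrier proportions per subject, not allele
frequencies; SNP genotypes must be collapsed to carrier counts before input.

Two structural identities are useful sanity checks and are enforced by the
test suite: when case and control frequencies are equal the posterior reduces
exactly to the baseline risk (the variant carries no information), and a
control frequency of zero drives the posterior to 1.

## Credible intervals

Percentile bounds f₂.₅ and f₉₇.₅ for each carrier proportion are the Wilson
score interval evaluated at z standard deviations (default z = 2, the
mean ± 2σ convention for the 2.5th/97.5th percentiles; z is configurable,
e.g. 1.959964 for the exact normal 95% quantile). The bounds are pushed
through the Bayes formula pairing the low case frequency with the high
control frequency for the lower penetrance bound and vice versa for the
upper, which makes the interval conservative. The Wilson interval is used
directly as the percentile pair rather than resampling from a fitted prior:
it is the closed form the score method defines, its lower bound is exactly 0
at zero successes, and it behaves well at the small counts typical of rare
CNVs.

Implementation note: the Wilson bounds are computed by statsmodels
(`proportion_confint(..., method="wilson")`, with the tail mass α = 2·Φ̄(z)
so any z is supported); the test suite checks them against an independently
written closed form over every (k, n) with n ≤ 50 to 1e-10.

## Numerical choices and degenerate inputs

- All outputs are clamped to [0, 1] and the (lower, median, upper) ordering
  is enforced defensively after clamping; an upper bound of 1.0 on a printed
  estimate is a clamp, not rounding.
- Zero carriers in **both** arms raises an undefined-estimate error (the
  posterior is 0/0); batch mode flags such rows and continues, single-variant
  mode fails loudly with exit code 2.
- Display rounding follows the convention of the published comparison
  tables — medians to 3 decimals, interval bounds to 2 — and is off by
  default so machine-readable output round-trips at full precision.
- Cross-study aggregation is the unweighted arithmetic mean of study medians
  per variant (with min/max recording the spread); a sample-size-weighted
  mean is available via the `weights` argument. Unweighted is the default
  because an "average across studies" makes no weighting claim.

## Validation statistics

Agreement between published estimates and recomputed ones is summarised
three ways over a set of paired (median, lower, upper) triples:

1. Pearson correlation of medians, with a two-tailed p-value from
   t = r·√((n−2)/(1−r²)) at n−2 degrees of freedom.
2. Pearson correlation of per-variant coefficients of range,
   (U − L)/(U + L), a scale-free width summary, computed for both sources.
3. Σ(O−E)²/E with published medians as expected and recomputed medians as
   observed, df = n−1. Applying a count statistic to proportions is
   descriptive agreement, not inference, and is labelled as such. A Yates
   continuity correction is available behind a flag but off by default:
   with |O−E| < 0.5 everywhere, subtracting 0.5 from every deviation zeroes
   the statistic identically, so the corrected form is uninformative here.

The bundled 21-CNV table stores the published values exactly as printed.
Two rows print a lower credible bound of 0.79 above their upper bounds of
0.21/0.19 — reading 0.079 restores ordering around the 0.131/0.123 medians,
so the loader repairs any mis-ordered bound by a single decimal shift when
that fixes the ordering, warns, and otherwise raises. On this table the
recomputed-vs-published statistics are r = 0.992 for medians (P < 0.001),
χ² = 0.041 (P ≈ 1), and r = 0.917 for the coefficients of range (P < 0.001).
The coefficient of range is highly sensitive to the 2-decimal rounding of
the printed bounds (a lower bound printed as 0.02 may be anything in
[0.015, 0.025), moving the coefficient by several hundredths), so
correlations computed from printed tables should be read with that
granularity in mind.

## Synthetic data generator

`simulate_case_control` draws carriers_cases ~ Binomial(n_cases, f_cases)
and carriers_controls ~ Binomial(n_controls, f_controls) independently per
replicate from a seeded generator; `analytic_penetrance` evaluates the Bayes
formula at the true frequencies as ground truth. The generator emulates
sampling noise only — no ascertainment bias, population stratification,
genotyping error, or linkage between variants — so passing recovery and
coverage checks demonstrates correctness of the estimator arithmetic, not
robustness to those real-data features.

The default recovery/coverage experiment uses schizophrenia-scale
conditions: true carrier frequencies 0.5% in cases and 0.1% in controls,
baseline risk 0.7%, 50,000 subjects per arm, 500 replicates. Under these
conditions the mean estimated median falls within 10% relative error of the
analytic truth and the z = 2 interval covers the truth in ≥ 90% of
replicates. Coverage is asserted loosely (≥ 90% rather than a nominal 95%)
because the propagated interval is an approximation whose exact coverage is
not characterised; empirically it is conservative (~99% under the default
conditions).

## Known limitations

- One variant at a time: no combined penetrance for carriers of multiple
  variants, and no liability-threshold or frequentist alternatives.
- Published per-variant medians cannot be recomputed from the bundled table
  alone, since it intentionally carries no per-row carrier counts or
  baselines; the table supports the agreement statistics only.
- The χ² comparison treats proportions as counts, following the validation
  procedure it reproduces; it should not be used for formal inference.
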