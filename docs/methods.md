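# Methods

## The misdiagnosis mixture model

The package models a matched case-control study of a binary candidate
causal factor.  Diagnosed cases are a latent mixture: with probability γ a
case is *apparent* (a genuine patient of some other disease) and carries
the factor with the control prevalence θ₀; with probability 1−γ it is
*genuine* and carries it with prevalence θ₁\*.  The working assumptions
are the standard ones for this kind of sensitivity analysis:

1. only genuine cases are associated with the factor;
2. apparent cases are exchangeable with healthy controls with respect to
   the factor;
3. misdiagnosis depends only on true clinical status (not on confounders,
   disease duration, or site);
4. controls are correctly classified as healthy;
5. when the factor is read through a binary classifier, its sensitivity
   π_se and specificity π_sp are identical for all individuals.

Under these assumptions the case group's marginal factor prevalence is
θ₁ = γθ₀ + (1−γ)θ₁\*, and with an imperfect classifier the
observed-positive probabilities in cases and controls are

    p₁ = π_se[γθ₀ + (1−γ)θ₁*] + (1−π_sp)[γ(1−θ₀) + (1−γ)(1−θ₁*)]
    p₀ = π_se·θ₀ + (1−π_sp)(1−θ₀)

Both classifier formulas reduce exactly to their perfect-test counterparts
at π_se = π_sp = 1; this reduction, and the linearity/monotonicity of θ₁
in γ, are enforced by property tests.

Effect sizes are parameterised by the true odds ratio Δ_T between genuine
cases and controls; θ₁\* = Δ_T θ₀ / (1 − θ₀ + Δ_T θ₀).  The inversion is
used unchanged for protective factors (Δ_T < 1), giving θ₁\* < θ₀.  At the
degenerate boundaries θ₀ ∈ {0, 1} the odds ratio carries no information
and θ₁\* is pinned to θ₀ with a warning.

## Sampling model and test

Each replicate study draws the observed-positive counts as two independent
binomials with fixed group sizes, Binomial(n₀, p₀) and Binomial(n₁, p₁) —
the product-binomial design in which group sizes are design constants.
`sample_latent_table` provides the equivalent hierarchical draw (binomial
apparent/genuine split, per-stratum true factor status, per-individual
classification); marginalising it reproduces the direct sampler's
distribution, which the test suite checks by a two-sample comparison at
20,000 replicates and by matching the closed-form mean.

Association is tested with Pearson's χ² (1 df).  **No continuity
correction is applied by default**: the uncorrected statistic reproduces
the reference threshold matrices exactly on spot checks, while the Yates
variant (available via `yates=True`) systematically lowers thresholds by
0.03–0.09 at n = 100.  A replicate whose table has an empty row margin
(probable when prevalences are near 0 or 1 and groups are small) carries
no evidence against independence; it is scored as "no rejection" (p = 1)
rather than dropped, keeping the power denominator fixed at the replicate
count.  The scalar test is validated cell-by-cell against a naive
textbook implementation and against `scipy.stats.chi2_contingency`; the
vectorised production path (the N(ad−bc)² closed form) is validated
against the scalar one, degenerate tables included.

## Power curves and the tolerance threshold

Power is the proportion of replicates with p < α (default α = 0.05,
default 10,000 replicates), reported with its binomial standard error
√(p̂(1−p̂)/R).  A power curve evaluates this on a γ grid from 0 to 1 in
steps of 0.01.  The true power is non-increasing in γ (at γ = 1 it equals
α by construction), but the raw Monte-Carlo curve is noisy, so the
threshold search first applies an antitonic regression
(`sklearn.isotonic.IsotonicRegression`, decreasing) and then takes the
largest grid γ whose smoothed power is at least the 80% target; `None` is
returned when even γ = 0 falls short.  Smoothing makes the threshold
stable at reduced replicate counts; a raw mode thresholds the unsmoothed
curve for comparison.  Thresholds are grid-valued, so they are compared in
exact 0.01 steps rather than with floating-point tolerances.

## Random-number discipline

All streams derive from a root seed through `numpy.random.SeedSequence`
spawn keys.  The key of a grid cell is built from the *parameter values*
(probabilities discretised at 10⁻⁴, plus the group sizes), not from the
cell's position, and the per-γ index is appended inside a curve.  Hence
results are independent of grid order or subsetting, a cell re-run alone
reproduces its in-grid value bit-for-bit, and two grids that describe the
same scenario (e.g. the perfect-classifier column of the classifier sweep
and the corresponding cell of the effect-size sweep) agree exactly, not
just statistically.

## Default study conditions

The scenario grids mirror the reference simulation design: effect sizes
Δ_T ∈ {1.25, 1.5, 2, 3, 5, 10}, control prevalences θ₀ ∈ {0.05, 0.1,
0.25, 0.5}, group sizes n ∈ {100, 250, 500, 1000, 2500, 5000}, γ step
0.01, 10,000 replicates, α = 0.05, target power 80%.  The classifier sweep
fixes Δ_T = 3, θ₀ = 0.25 and crosses π_se, π_sp ∈ {0.8, 0.9, 0.925,
0.975, 1.0}.

The two bundled application fixtures transcribe published summary
parameters:

* **steiner_snps** — five SNP associations (θ̂₀ from 0.08 to 0.56, odds
  ratios 0.84–1.63) from 201 controls vs 305 ME/CFS patients.  These are
  allele-based effects: θ₀ is a non-reference allele frequency and the
  odds ratio is allelic, so each genotyped subject contributes two
  chromosomes and the simulated 2×2 table holds 2n₀ = 402 and 2n₁ = 610
  alleles (`copies_per_subject = 2`).  Person-level simulation would cap
  the strongest association's power at ~0.63 and cannot reproduce the
  reported findings, whereas the expected allele tables reproduce the
  studies' printed χ² p-values to the first significant digit.
  Genotyping error is neglected (π_se = π_sp = 1), as in the original
  analysis.
* **cliff_serology** — six herpesvirus seroprevalences (θ̂₀ 0.34–0.97,
  odds ratios 0.65–1.60) from 107 controls vs 251 severely affected
  patients.  Seropositivity came from a mean + 2σ cut-off; under a normal
  seronegative population that implies specificity ≈ 0.975, and
  sensitivity is assumed equal (π_se = π_sp = 0.975), overridable on the
  command line.

The printed confidence intervals and p-values ride along in the fixtures
for provenance and transcription checks only; simulations use only θ̂₀,
Δ̂_T, the group sizes and the classifier parameters.

## What the simulations do and do not emulate

The generator reproduces the sampling noise of a two-group binomial design
under the mixture assumptions above.  It does not model confounding,
covariate matching, contaminated or misdiagnosed *controls*, multiple
genuine-case subtypes with heterogeneous effects, genotype-level tests
(Hardy-Weinberg departures are invisible to an allele-count binomial), or
correlation between factors tested in the same cohort.  Agreement with the
reference results therefore validates the power arithmetic under the
stated model, not the model's fit to any real cohort.

## Numerical and design notes

* The vectorised χ² path works on counts, never materialising per-table
  arrays; a full 101-point curve at 10,000 replicates costs ~1 s,
  independent of group size, so no scaled-down problem sizes are needed
  anywhere.
* Scenario validation is eager and names the offending field; supplying
  both Δ_T and θ₁\* is an error rather than a silent priority rule.
* `estimate_power` with a bare seed derives a scenario-keyed substream, so
  independent single-point calls are also reproducible and
  order-independent.
* Thresholds serialize as empty CSV cells / JSON `null` when the target
  power is unreachable.
* Known limitation: for the strongest SNP association the tolerance
  threshold computed here (γ_max ≈ 0.13–0.14 at 80% power) sits somewhat
  above the originally reported reading (≈ 0.09) while every other
  reported quantity of both re-analyses is reproduced within Monte-Carlo
  noise; the power curve is very flat near the crossing (slope ≈ −0.007
  per 0.01 γ), which makes this threshold the least stable quantity in
  the suite.
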