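# Methods

## The problem and the model

A congenic interval associated with a quantitative trait (here: white
adipose tissue weight and related obesity traits in mice) contains many
genes; expression differences alone cannot distinguish a gene that *drives*
the trait from one that merely *responds* to it or varies in parallel. The
causal inference test (CIT) addresses this with conditional regressions on
triplets (diplotype *D*, expression *R*, trait *T*):

- Model 1: `T = β₀ + β₁·D + ε` — Test 1: is D associated with T?
- Model 2: `R = β₀ + β₁·D + β₂·T + ε` — Test 2: D associated with R given T?
- Model 3: `T = β₀ + β₁·R + β₂·D + ε` — Test 3: R associated with T given D?
- Model 4: `T = β₀ + β₁·D + β₂·R + ε` — Test 4: D associated with T given R?

All fits are ordinary least squares; the p-value for a tested term is the
partial F comparing the full model against the model without that term.
Under categorical coding the diplotype contributes two contrast columns
(2-df test); under additive coding it enters as C-haplotype dosage 0/1/2
(1 df). Categorical is the default: it makes no additivity assumption for a
three-class genotype, and it makes Test 1 identical to the one-way ANOVA of
the trait screen by construction.

A mediated (causal) chain D→R→T predicts Tests 1–3 reject while Test 4 does
not — conditioning on the mediator absorbs the genotype effect. The
independent model (D→R and D→T in parallel) predicts Test 3 fails and
Test 4 rejects. "Independence declared by non-significance" in Test 4 is a
deliberate simplification: the original CIT literature uses an equivalence-
style omnibus test there, but the present battery mirrors the simpler
nominal-α reporting convention of the study design this package reproduces;
an equivalence-test alternative would be a natural extension.

## Relationship labelling

With α = 0.05 and a marginal band [0.05, 0.06) for Test 3, the classifier
is a total function of the p-value pattern:

| p1    | p2    | p3          | p4    | reverse battery | label           |
|-------|-------|-------------|-------|-----------------|-----------------|
| ≥ α   | —     | —           | —     | —               | not_assessed    |
| < α   | ≥ α   | not run     | not run | fully passes  | reactive        |
| < α   | ≥ α   | not run     | not run | otherwise     | not_assessed    |
| < α   | < α   | < α         | ≥ α   | —               | causal          |
| < α   | < α   | in band     | ≥ α   | —               | causal_marginal |
| < α   | < α   | ≥ α         | < α   | —               | independent     |
| < α   | < α   | < α         | < α   | fully passes    | reactive        |
| < α   | < α   | < α         | < α   | otherwise       | undetermined    |
| < α   | < α   | ≥ α         | ≥ α   | —               | undetermined    |

The *reverse battery* is the same four tests with R and T exchanged; it
"fully passes" when its Tests 2 and 3 reject and its Test 4 does not. Under
a true reactive chain D→T→R, R is independent of D given T, so the forward
battery stops at Test 2 while the reverse battery passes — that is the
designed route to a reactive call. Note an algebraic degeneracy of the
role swap: the reverse Test 2 is the forward Test 4's model and the reverse
Test 4 is the forward Test 2's model, so a triplet whose forward battery
rejects *all* of Tests 2–4 can never also have a fully passing reverse
battery; that all-significant pattern is therefore reported as
`undetermined` unless external reverse evidence is supplied to the
classifier, which keeps the labelling rule honest about what the data can
and cannot distinguish. Early stopping after a failed Test 2 reports
Tests 3–4 as not assessed (NA), matching the screening report layout.

No multiple-testing correction is applied across traits or gene×trait
pairs; all decisions are at the nominal 5% level with the marginal band
flagged, mirroring the reporting conventions of the reproduced study
design.

## Litter residualization and the trait screen

Littermates share maternal environment; in the selected-set design the
litter factor is significant for most traits. Every variable is therefore
residualized on litter (OLS of the one-way litter-factor model, i.e.
per-litter mean subtraction; a singleton litter gets residual 0) before any
diplotype comparison, and residualization is idempotent with residuals
summing to zero within each litter. The subsequent one-way ANOVA and
Tukey HSD use error df = N − 3 (diplotype classes only), not
N − 3 − (litters − 1): the residualize-then-ANOVA workflow treats adjusted
values as data. This makes the screen mildly anti-conservative (the
simulated Test 1 type-I rate at the study's litter structure is ≈ 0.05–0.06
rather than exactly 0.05), which is the documented cost of matching the
two-stage procedure; a mixed model with a random litter effect is a
non-goal.

Tukey ordering strings sort the three diplotypes by descending adjusted
mean (ties broken C/C, B/C, B/B) and join adjacent groups with `>` when the
Tukey-adjusted p is below α, else `≥`. `reconstruct_groups` rebuilds
per-individual groups from printed summary statistics (means, common SE of
the mean, n) so summary-level reports can be replayed through the same
code path: each group is `mean + SE·√n · u` with `u` a fixed zero-mean,
unit-SD pattern, making the pooled MSE exactly `n·SE²`.
`grouping_rounding_ambiguous` flags rows where half-ulp perturbations of
the printed means move an adjacent comparison across the studentized-range
critical value — for such rows the printed string is not recoverable from
printed precision, and replay tests treat them as within-envelope rather
than exact.

## Differential-expression filter

The DE rule is `max(FPKM across diplotypes) > 0.1` **and**
`|log2(FPKM_CC / FPKM_BB)| ≥ 0.58`. The floor applies to the maximum, not
to each diplotype: a gene essentially silent in one homozygote (FPKM 0.06)
but expressed in the other is a legitimate hit, and an all-diplotype floor
would discard exactly the strongest candidates. Only the C/C-vs-B/B
contrast enters the decision; the B/C column is reported but not filtered
on, since heterozygote contrasts are noisier and not required by the rule.
Fold changes with a zero FPKM are flagged (warning, not silently dropped)
and never called DE. Coordinates are 1-based inclusive bp with any-base
overlap against the target region (default 59.4–65.3 Mb of chromosome 2).

## qPCR quantification

Standard curves regress mean Ct on log10(input amount) over a four-point
serial dilution (default 20, 4, 0.8, 0.16 ng). Efficiency is
`10^(−1/slope) − 1`; a perfect doubling per cycle gives slope −3.3219 and
efficiency 1.0. Curves with non-negative slope are flagged invalid.
Triplicate Ct values are averaged arithmetically before any transformation
(conventional; the alternative of averaging amounts changes third-decimal
digits at realistic replicate noise). The "composite level" of the two
endogenous controls is their geometric mean — the standard multi-reference-
gene normalization, chosen here as a design decision because the source
workflow does not define the composite. The 2^−ΔΔCT route is exactly
equivalent to the standard-curve route when both amplification efficiencies
are 100%, and the suite verifies that equivalence. Reported levels are
rescaled so the B/B mean equals 1; litter-adjusted least-squared means may
be negative and are never clamped. The CIT consumes raw normalized levels
and residualizes internally.

## Synthetic data

The generator emulates the study design: `n_sets` litter-matched sets of
three F2 males, one per diplotype, drawn from `n_litters` litters assigned
round-robin (the real design: 5 sets from 4 litters, so one litter
contributes two sets — the round-robin choice reproduces that pattern and
is the package's resolution of an unstated detail). A per-litter shift
`N(0, σ_litter)` is added to both R and T, making litter a genuine shared
confounder of the R–T association that residualization must remove.
Structural equations per architecture are in `synthetic.py`'s docstring;
dosage is coded 0/1/2.

Default parameters — a₀ = 1, a₁ = 1, b₀ = 0, b₁ = 1, σ_r = σ_t = σ_litter
= 1 — put the genotype effect at one residual SD per dosage step, a strong
but realistic eQTL-scale effect; they are the package's standard conditions
for its operating-characteristic simulations (with `n_sets = 20`, i.e.
n = 60, and 500 replicates), under which the causal architecture is
labelled causal in ≈ 85–90% of replicates, the independent architecture is
falsely labelled causal in < 1%, and the reactive architecture is labelled
reactive in ≈ 85–90%. What the generator does **not** emulate: genome-scale
expression (one mediator plus optional extra columns only), non-Gaussian
trait distributions, dominance at the diplotype, litter-by-genotype
interaction, and measurement error in D. Passing recovery tests therefore
shows the battery works when its linear-Gaussian assumptions hold at
realistic design sizes — not that it is robust to their violation.

## Numerical choices and degenerate inputs

- Partial F-tests compare full/reduced residual sums of squares; a perfect
  full fit yields p = 0 (or p = 1 when the reduced fit is also perfect).
- Rank-deficient designs raise `CollinearityError` naming the offending
  term; a regressor identical to the response does too. No silent
  pseudo-inverse fits.
- ANOVA on identical groups returns (F = 0, p = 1); zero within-group
  variance with unequal means returns (∞, 0) rather than crashing.
- Pooled-variance t-test with zero pooled variance returns p = 1 (equal
  means) or 0.
- Missing values are dropped pairwise per analysis in the screening and
  battery entry points.
- Reports are written atomically; a completed report is never overwritten
  unless explicitly requested.

## Problem sizes used in the shipped analyses

Fixture replays are instantaneous. Simulation-based checks use 500
replicates at n = 60 (recovery rates, type-I calibration), 200 seeds at
n = 15 for the null-correlation check, and single datasets of n = 600 for
conditional-independence signatures — sizes at which the Monte-Carlo error
of a rate is under ±3 percentage points.

## Known limitations

- The reactive/undetermined boundary is information-limited (see the
  degeneracy note above): forward-all-significant triplets cannot be
  resolved from the forward battery alone.
- Error df = N − 3 after residualization slightly inflates Test 1's size
  (see above).
- No FDR control across the gene×trait grid; the battery reports nominal
  p-values.
- The DE filter consumes precomputed FPKM tables; alignment and FPKM
  estimation are out of scope.
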