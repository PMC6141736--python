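# Methods

## The CNI processing tree

The model assumes every binary dilemma judgment is produced by one of three
latent routes, tried in a fixed order. With probability *C* the response is
outcome-driven: the agent acts exactly when the action's benefits exceed
its costs. Failing that, with probability *N* the response is norm-driven:
the agent acts exactly when the norm is prescriptive. Failing both, a
general disposition applies: inaction with probability *I*, action with
1 − *I*, regardless of outcomes and norms. The four design cells therefore
have the action probabilities listed in the README; two algebraic
consequences are used as invariants throughout the code and tests:
p₁ − p₂ = C, and p₃ − p₁ = p₄ − p₂ = (1−C)·N (the model's single degree of
freedom per group: 3 parameters describing 4 free cell proportions).

Assumptions worth keeping in mind: responses are treated as independent
Bernoulli trials both across items and across participants, and counts are
**pooled within group** before fitting (the convention of aggregate MPT
software). Pooling is what makes the degrees of freedom come out as
4·groups − free parameters (1 for a pooled fit, 2 for a two-group free
fit); it also means the fitted parameters describe the group aggregate,
not any individual, and that between-participant heterogeneity appears as
extra-binomial dispersion the G² test can pick up at very large samples.

## Estimation and inference

The product-binomial log-likelihood is maximized with L-BFGS-B on the box
[0,1]³ᴳ using the analytic gradient, started from the moment-inversion
solution (C = p̂₁ − p̂₂, N = (p̂₃ − p̂₁)/(1 − C), I = 1 − p̂₂/((1−C)(1−N)))
plus 10 uniform random restarts; convergence tolerance 1e-10 on the
log-likelihood. The restarts are insurance against starts trapped on the
box boundary; the problem itself is smooth and three-dimensional per
group. Estimates within 1e-4 of the box edge are flagged as boundary
solutions. Equality and fixed-value constraints are implemented by mapping
a reduced free-parameter vector onto the per-group parameter matrix, so
constrained and unconstrained fits share one code path.

G² = 2·Σ obs·ln(obs/exp) over all 8·groups cells with 0·ln 0 ≡ 0 and
expected counts = fitted probabilities × observed cell totals; negative
values from roundoff are clipped to 0. ΔG² between nested fits is referred
to χ² with df = the number of free parameters removed. Confidence
intervals are Wald, from the observed information (central finite
differences of the analytic score, step 1e-5, one-sided at the box edge),
clipped to [0,1]; profile-likelihood intervals (bisection on the ΔG² = 3.84
contour) are available via `fit_ml(..., profile_ci=True)` for boundary
cases, where Wald intervals are unreliable.

Missing responses are tolerated: cells simply carry different totals, which
the product-binomial likelihood does not mind. Empty cells are an error.

## Process dissociation and the classical stack

PD uses only proscriptive items: benefits > costs is *incongruent* (the
two moral principles conflict), benefits < costs is *congruent*. U and D
follow the algebra in the README; per-participant proportions over 6 items
make D noisy, and values outside [0,1] (possible since U can be negative)
are deliberately retained — clipping would bias the downstream
regressions. Participants with U = 1 have undefined D and are dropped
pairwise from D analyses only; the count of such cases is reported.
U and D are z-scored (sample SD, n−1) over the participants with defined
values before correlation/regression analyses.

The choice score is the **count** (0–6) of action judgments on the six
incongruent items, not the 0–1 mean: the conventional neutral reference
point of 3 and the reported scale of group means only make sense on the
count scale. This is stated prominently because the same quantity is often
loosely described as an "average".

Hierarchical regression z-scores the outcome and all predictors —
including 0/1 gender — before OLS, which makes the reported coefficients
the "Beta" column of standard statistics packages; whether to z-score a
binary predictor is a convention, and this is the documented choice here.
ΔR² is the difference of cumulative R², tested with the usual F-change
statistic (df1 = predictors added, df2 = n − k − 1). Cronbach's α uses
sample variances. The median split sends values strictly above the sample
median to "high" and ties at the median to "low" — with integer PSS totals
this is the rule that yields a slightly larger low group, as observed in
studies using this design; the rule matters and is therefore explicit.
All p-values are two-tailed.

## The synthetic-data generator

The generator emulates the study design the analyses target: default 197
participants; integer ages from a rounded truncated normal on [18,22]
(mean 19.49, SD 0.83); gender Bernoulli(0.345), coded 1 = male; PSS totals
with mean 26.51 and SD 5.33. At item level the ten PSS items follow a
one-factor Gaussian model rounded and clipped to the 0–4 Likert scale; the
latent mean, loading, and residual SD are calibrated by fixed-point
iteration against the exact discretized-normal moments (with inter-item
covariance attenuated by the squared location-sensitivity of the
discretization), so the observed items hit the target total mean, total
SD, and an expected Cronbach's α of 0.80 despite the coarse scale.

Each participant's CNI parameters sit on the logit scale,
logit(P_i) = logit(P₀) + β_P·z_i + ε_i with ε_i ~ N(0, σ_between), where
z_i is the sample-standardized PSS total. The logit link keeps parameters
in (0,1) for any effect size; baselines at exactly 0 or 1 are rejected.
Defaults: C₀ = 0.131, N₀ = 0.145, I₀ = 0.451 (plausible pooled values for
this battery), β_C = β_N = 0, β_I = 0.2, σ_between = 0.3. The stress
effect sizes are **illustrative**: no generative values exist to anchor
them, and β_I = 0.2 was chosen so a study-sized sample shows a negative
stress–choice correlation of realistic magnitude (≈ −0.1 to −0.2).
Responses are independent Bernoulli draws from each participant's tree
probabilities.

What the generator does *not* emulate: item-specific difficulty or content
effects (all six dilemmas within a cell are exchangeable), within-
participant response dependence beyond the shared (C,N,I), response times,
and any non-stress covariate structure (age and gender are independent of
everything). Passing tests therefore certify the estimation machinery and
the qualitative stress→inaction signature under the model's own
assumptions — not that real dilemma data satisfy those assumptions.

## Verification design

Because no raw data from the emulated study are public, acceptance is
property-based. The fitter is checked against an independent two-stage
exhaustive grid search (101³ coarse grid refined to ~2.5e-4 spacing; for
equality constraints the shared axis is scanned with per-group maxima);
χ² calibration of G² and of the equality ΔG² tests, Wald CI coverage, and
parameter recovery (bias/RMSE over n ∈ {50, 200, 2000} participants, 200
replicates; 500 replicates for calibration at 200 participants) run on
model-true simulated counts at the baseline parameters. The end-to-end
pattern check uses β_I = 0.4 at 1000 participants — an effect size and
sample chosen to give high power for the positive detections — and
requires the full qualitative signature (negative stress–choice r,
positive stress–D, null stress–U, I group difference with null C/N
differences) in ≥80% of 100 replicates, with the positive detections
falling to the α level when β_I = 0. Problem sizes were chosen so the
whole suite runs in a few minutes on one CPU.

## Known limitations

- Pooled fitting ignores participant heterogeneity; hierarchical/latent-
  trait MPT variants are out of scope.
- Wald intervals degrade near the parameter boundary; use the profile
  option there.
- The generator's stress link and noise scale are illustrative defaults,
  not estimates; conclusions about real effect sizes cannot be read off
  simulated runs.
- The grid oracle, not an external MPT program, is the independent check;
  its resolution bounds the tightness of the equivalence assertions
  (0.01 on parameters, 0.05 on ΔG²).
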