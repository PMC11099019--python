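# Methods

## The model

The core estimand is the association between a binary in-utero exposure and
a 10-dimensional vector of epigenetic-aging outcomes measured on children
clustered within mothers:

```
Y_ij = β0 + β1 T_ij + β2' X_ij + b_j + ε_ij
b_j  ~ MVN(0, Σ_b)        ε_ij ~ MVN(0, Σ_e)
```

for child *i* of mother *j*. The outcome vector is ordered (EAA_PedBE,
EAA_Wu, EAA_Horvath, EAA_Hannum, EAA_SkinBlood, EAA_PhenoAge, EAA_GrimAge2,
EAA_DNAmTL, DunedinPACE, DunedinPoAm38): eight residual-based age
accelerations plus two pace-of-aging rates. T is the exposure indicator,
X = (gravida, male sex, wet-season birth, epithelial fraction, fibroblast
fraction); the immune-cell fraction is the reference category and is never
included. Σ_b captures shared family effects (genetics, household
environment) jointly across outcomes; Σ_e is fully unstructured because
clocks trained on overlapping CpG sets have strongly correlated errors.

Assumptions: random intercepts and residuals are independent multivariate
normals; covariate effects are common across siblings; exposure acts
additively on each outcome. Both b_j and ε_ij being 10-dimensional with
free covariance is what lets one model absorb the multiplicity across
outcomes instead of ten univariate fits.

### Priors and sampler

Every fixed-effect coefficient gets an independent N(0, v0) prior with
v0 = 10⁹ (effectively flat); Σ_b and Σ_e get IW(ν, S) priors with ν = 10
and S = I₁₀, in the convention where the IW mean is S/(ν − p − 1). With
ν = p = 10 the prior mean is undefined; this is accepted as a deliberately
weak prior and only ν ≥ p is enforced. Whether the flat coefficient prior
should also cover the intercept and covariate block is a judgment call; we
apply it to all fixed effects, which is the natural reading of a
"non-informative prior on the regression coefficients".

All four full conditionals are conjugate, so the posterior is explored by
plain Gibbs sampling:

1. stacked coefficients: MVN with precision Σ_e⁻¹ ⊗ Z'Z + I/v0 on the
   column-stacked q×10 coefficient matrix (Z = [1, T, X], q = 7);
2. random intercepts: per cluster j, precision n_j Σ_e⁻¹ + Σ_b⁻¹, mean
   precision⁻¹ Σ_e⁻¹ Σ_{i∈j}(y_ij − fitted);
3. Σ_b ~ IW(ν + J, S + Σ_j b_j b_j');
4. Σ_e ~ IW(ν + N, S + Σ_ij ε_ij ε_ij').

Initialization is deterministic — per-outcome OLS for coefficients, zeros
for b, identity covariances — so a fit is fully reproducible from the seed.
Default chain: 20 000 sweeps, 5 000 burn-in, no thinning. The reduced
configuration used in replicate experiments (4 000 / 1 000) was chosen
because the chain's effective sample sizes there (several hundred to a few
thousand per coefficient) already pin posterior means well below the width
of the intervals being checked.

Correctness is established three ways in the test suite: conditional
moments against dense joint-Gaussian conditioning oracles; fixed-covariance
no-random-effect fits against closed-form conjugate/GLS solutions; and a
Geweke-style check that forward simulation from priors+likelihood and
successive-conditional Gibbs simulation share the marginal moments of the
exposure coefficient and residual variances (run with proper test priors,
v0 = 1 and IW(4, I₂), since a 10⁹-variance prior cannot be
forward-simulated meaningfully).

### Inference and diagnostics

Intervals are highest-posterior-density: the shortest window containing
⌈0.95·n⌉ order statistics of the retained draws, ties resolved to the
lowest start. An effect is "significant" iff its HPD interval excludes
zero. Effective sample sizes use the initial-monotone-positive-sequence
autocorrelation estimator on single chains; a constant chain is flagged
NaN. Trace plots are available from the results object.

## Clock engine

A clock definition is (intercept, CpG→weight map, transform, CpG→reference
median map, minimum coverage). Scoring enforces the coverage rule — below
80 % present CpGs is an error naming the sample, not a silent NaN — then
fills the remaining gaps with the definition's reference medians, takes the
weighted sum, and applies the transform. The pediatric log-linear age
transform maps linear scores s to (A+1)e^s − 1 below the calibration age A
and A + s(A+1) above it; its forward map is implemented too and round-trips
to 1e-12. Published coefficient sets are not bundled (several are not
freely redistributable); any clock can be loaded from a `cpg,weight,median`
CSV with a JSON sidecar. The shipped toy clocks exist to exercise the
machinery and the synthetic pipeline.

## Deconvolution

Per sample, beta values on the reference CpGs are regressed on the
reference profiles by iteratively reweighted least squares with Huber
weighting (tuning constant 1.345, ≤ 50 iterations, coefficient tolerance
1e-8, no intercept), in the robust-partial-correlation style; negative
coefficients are truncated to zero and the vector renormalized to the
simplex. Truncate-then-renormalize was chosen over constrained optimization
for transparency; tests bound its deviation from a non-negative
least-squares solution (≤ 1e-3 under small truncation-triggering noise —
the two approaches genuinely diverge when a large negative component is
truncated, which is why the bound is stated only for small perturbations).

## EAA

EAA is the residual of OLS of clock estimate on age, computed in centered
form so residuals are exactly mean-zero and age-orthogonal. Residualization
pools both exposure groups. The pace measures are already rates and are not
residualized by default (a `residualize_pace` flag exists for sensitivity
runs). Outcomes are not standardized; coefficients stay on natural scales.

## Synthetic cohort generator

The generator emulates the study conditions: each mother contributes two
(configurable) same-sex children, exactly one exposed, the exposed sibling
strictly older (exposure during a past drought forces the ordering). Ages
are uniform on (7.0, 9.61) for exposed and (1.81, 7.0) for unexposed
children; sex is female with probability 0.54; birth season wet with
probability 0.59; gravida is a rounded zero-truncated normal(3.08, 2.21)
for the exposed pregnancy, incrementing by one per later sibling; cell
proportions are Dirichlet with means (0.24, 0.02, 0.74) and concentration
50. The default exposure-effect truth is (0, 0, 0, 1.34, 0, 0, 1.31,
−0.12, 0, 0) over the canonical outcome order — nonzero on the Hannum-EAA,
GrimAge2-EAA and telomere outcomes. Per-outcome total SDs default to
(0.69, 1.21, 1.92, 3.35, 0.73, 0.69, 1.77, 0.28, 0.14, 0.07), split evenly
between Σ_b and Σ_e with exchangeable correlation 0.3 within each — a
one-time choice giving intraclass correlations of 0.5, in the range
expected for sibling designs; the telomere and pace dispersions follow the
clock-scale spread rather than an EAA table row that appears to duplicate
another clock's values.

Beta matrices are built inversely: a clock's target output is mapped back
through the transform to the linear scale and the shortfall relative to a
0.5-baseline is spread equally across the clock's CpGs, so noise-free
matrices score back to the targets exactly; unreachable targets raise
rather than clip. Default targets track chronological age for age clocks,
a slowly shortening telomere (7.19 − 0.016·(age − 6.72)), and pace rates
drifting mildly with age (1.32 − 0.025·Δage and 1.16 + 0.006·Δage). Toy
clocks carry 50 CpGs each so the inverse construction has headroom across
the whole age range.

What the generator does **not** emulate: array-level artifacts (probe
bias, batch effects, detection failures), genome-scale CpG counts, realistic
between-CpG correlation within a clock, or non-normal outcome tails. Tests
passing on this generator therefore validate the estimation machinery —
linear scoring, residualization, the sampler's frequentist calibration —
not the biological fidelity of any particular published clock on real
saliva arrays.

One structural consequence worth knowing: because exposed siblings are
strictly older, exposure and age are strongly collinear. In the full
simulate-score-residualize pipeline part of an injected exposure effect is
absorbed by the age regression, attenuating the fitted effect — the same
limitation the sibling design has on real data. Parameter-recovery
experiments therefore generate the outcome vector directly from the mixed
model, which is also how coverage of the generating truth is assessed.

## Numerical choices and edge cases

- Coverage threshold 0.80 is enforced as an error and is configurable per
  clock definition.
- HPD requires ≥ 20 draws; the equal-width tie is broken to the lowest
  start index.
- Rainfall z-scores use the sample SD (ddof = 1) over the historical
  same-calendar windows, excluding the target window; zero historical
  variance is an error rather than ±inf.
- Cohort validation rejects < 2 mothers, age ranges outside (0, 10],
  non-simplex cell means, asymmetric or indefinite covariance inputs.
- Descriptive tables round percentages to whole percent and report
  mean (SD) at two decimals.
- The pipeline writes every artifact plus a SHA-256 manifest; two runs with
  the same seed produce identical computed artifacts.

## Known limitations

- Single-chain sampling only; between-chain diagnostics (R-hat) are out of
  scope, though chains export cleanly to ArviZ.
- No missing-outcome handling in the mixed model; the outcome table must be
  complete.
- The deconvolution ships only a synthetic 3-type reference; results on
  real saliva require a user-supplied reference panel.
- The HPD-excludes-zero rule is a per-outcome marginal decision; the model
  reduces, but does not formally control, multiplicity across outcomes (one
  of the seven null outcomes will be flagged in roughly a third of runs at
  the 95 % level).
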