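# Methods

## Model

The package fits a bivariate Gaussian mixed model to the stacked vector
(Y, C) of standardized residual outcome and covariate traits on n
individuals.  Six random effects generate the data: polygenic intercepts
α0 (outcome) and β0 (covariate) and a polygenic slope α1 on the covariate
gradient, jointly N(0, Σg ⊗ K) with K the genetic relationship matrix; and
residual intercepts τ0, ε0 and slope τ1, i.i.d. N(0, Σe) per individual.
With D = diag(c), c being the standardized adjusted covariate, the
covariance of the stacked vector is

    V_YY = σ²α0·K + σα0α1·(KD + DK) + σ²α1·DKD + στ0²·I + 2στ0τ1·D + στ1²·D²
    V_YC = σα0β0·K + σα1β0·DK + στ0ε0·I + στ1ε0·D
    V_CC = σ²β0·K + σε0²·I

The null model (bivariate GREML) removes every α1/τ1 term: 6 free
parameters instead of 12.  The saturated parameterization — including the
slope–covariate-trait covariances σα1β0 and στ1ε0 — is the default; any
entry can be structurally zeroed through the initialization interface if a
sparser structure is wanted.

The gradient c is the observed covariate itself, not an external variable.
The model treats it as known when building V; this is the defining
approximation of the reaction-norm approach and the reason the residual
slope στ1² ("covariate-specific noise") must be carried alongside the
polygenic slope — dropping it biases the G–C estimate when residual
heteroscedasticity exists.

## Fixed-effect adjustment (stage 1)

Each trait is adjusted by ordinary least squares on its fixed-effect
columns before the mixed model sees it (two-stage estimation; the REML
stage keeps only per-trait intercepts).  Continuous confounders may enter
through fractional polynomials with the standard power set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ ln x, repeated powers add an x^p ln x
column, origin shift by the smallest-increment rule when x ≤ 0).  Selection
is the Royston–Altman closed test at level α (default 0.05): best-FP2
vs null on 4 df, vs linear on 3 df, vs best-FP1 on 2 df, cycling over
covariates until stable.  Principal components and other declared-linear
columns always enter linearly.  Biomarkers may be log-transformed before
adjustment.  Residuals are standardized to mean 0, variance 1 (population
denominator), making the Var[Y] = 1 decomposition exact by construction.

Missing data are handled by complete-case analysis per analysis group; the
stage-1 models are fitted on the full analysis group before any subgroup
splitting, so all subgroups share one adjustment.

## REML and the AI algorithm

The restricted likelihood is
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy], with P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹ and
the additive constant dropped; X holds per-trait intercepts.  V is linear
in the parameters, so every derivative matrix is fixed given K and c and
is kept in dense-or-diagonal block form, which keeps scores and the
average-information matrix at O(n²) beyond the single O((2n)³)
factorization per likelihood evaluation.

Each iteration proposes one step per damping level
λ ∈ {0, 0.1, 1, 10, 100} of a Levenberg-style damped system
(AI + λ·diag(AI)) δ = s, halving each proposal until it lies inside the
positive-definite cone and does not decrease the likelihood, then takes
the best proposal.  The first three iterations use only damped levels (a
stabilising warm-up in place of classical EM steps, which do not extend
cleanly to unconstrained covariance parameters).  Convergence is declared
when the best achievable improvement falls below tol = 1e-6; standard
errors come from the inverse AI matrix at the final parameters
(pseudo-inverse with a condition warning past 1e10).  Components are never
constrained in sign and a non-PD V is always signalled, never silently
regularized.  Default initialization is near-diagonal (0.3 polygenic /
0.7 residual intercept variances, 0.05 slopes); `warm_start_from_null`
embeds a fitted null model for cheaper full-model fits.

**The PD margin.**  "Unconstrained" estimation means the *components* are
free in sign; the covariance V they imply must still be invertible for
the likelihood to exist.  In small samples the restricted likelihood of
the 12-parameter full model frequently has no interior optimum: it keeps
increasing along a ridge that hugs the boundary of the PD cone, where V
approaches singularity.  Fits that crawl onto this ridge harvest spurious
log-likelihood — in null simulations at n = 500 the boundary replicates
carried likelihood-ratio statistics with roughly double the χ²₆ mean and
pushed the type-I error to ~13%, while strictly interior replicates were
calibrated.  The fitter therefore keeps V inside the cone with a small
margin (default `pd_margin = 1e-2` on the squared-Cholesky-pivot scale,
roughly the eigenvalue scale of a standardized-trait V; the margin is
inactive for typical interior solutions whose smallest eigenvalue is an
order of magnitude larger).  This mirrors what production GREML tools do
by bending non-invertible updates, truncates the most extreme spurious
likelihood-ratio statistics (see the calibration note under the validation
conditions — a residual small-sample inflation remains), and leaves
negative variance-component estimates (the expected behaviour under a
null interaction) fully available.  `MRNMFit.min_pivot_sq`
reports how close a solution sits to the margin.  Where a fit does stop
at the margin, the constrained optimum is a surface point rather than a
stationary point; the oracle-equivalence tests therefore assert agreement
with a derivative-free maximizer (over the same margin-constrained
domain) unconditionally for the null model and conditionally on strict
interiority for the full model.

## Inference

Full vs null is a likelihood ratio test on a plain χ² with df equal to
the added-parameter count (6 for the saturated structure); no 50:50
boundary mixture is used because components are unconstrained.  Statistics
are clamped at zero.  Subgroup p-values (random, seeded, size-balanced
partition; the partition depends on the id set, not input order) are
combined by Fisher's method (−2Σln p ~ χ²_2k); interaction variance
components are meta-analysed by fixed-effect inverse variance.  Bonferroni
uses a strict inequality at α/n_tests.  The RINT sensitivity analysis
(Blom offset 3/8, average ranks for ties) refits both models with the
rank-normalised outcome; a loss of the combined signal marks the
untransformed result as potentially driven by non-normality, while
variance components are always reported from the untransformed fit.
`rescale_to_outcome_scale` multiplies a proportion and its SE by the ratio
of residual variances under the full versus a reduced adjustment to state
effects on the original outcome scale.

Variance curves evaluate Var_g(c) = σ²α0 + 2c·σα0α1 + c²·σ²α1 (and the
residual analogue) on a grid with delta-method bands from the AI-inverse
(gradient (1, 2c, c²) per block); grid points outside the observed c range
are flagged as extrapolation.

## Synthetic data

The generator is the model read forwards.  Genotypes are Binomial(2, p)
hard calls in Hardy–Weinberg and linkage equilibrium with per-SNP MAF
uniform on a configurable range (no LD — the model operates through K, so
LD adds no testable structure).  Genetic values are built from per-SNP
effect triples drawn N(0, Σg/m) on standardized dosages, so the GRM
computed downstream from the same panel is exactly the kernel that
generated the data; a direct MVN(0, Σg ⊗ K) mode exists for
exact-kernel tests.  C is its genetic plus residual part (plus fixed
effects); the gradient used to build Y is the standardized *adjusted* C,
matching the fitted model's conditioning.  Optional confounders enter with
user-supplied effect functions, and an optional monotone sinh-arcsinh
transform, tuned by bisection on sample skewness, skews Y (default target
0.47, the skewness typical of questionnaire-derived symptom scores).  The
truth record stores every draw, so Y and C can be rebuilt exactly.

What the generator does not emulate: linkage disequilibrium, genotyping
missingness mechanisms beyond MCAR, ascertainment, binary/liability
outcomes, and real confounder distributions.  Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to real-data violations beyond the skew
scenario explicitly simulated.

## Validation study conditions

The statistical acceptance tests run at desk scale, sizes chosen so each
check is informative on one CPU:

- **Unit-variance check**: n = 10,000, m = 1000, components
  (0.2, 0.05, 0.7, 0.05), tolerance ±0.03 on the empirical Var[Y].
- **Oracle equivalence**: 20 instances, n ∈ [80, 100], m = 150; dense
  error-contrast likelihood oracle (1e-3) and Nelder–Mead polish oracle
  (1e-3, conditioned on interiority for the full model as described
  above).
- **Parameter recovery**: n = 1000, m = 250, 20 replicates, truth
  (σ²α0, σ²α1, στ0², στ1²) = (0.2, 0.1, 0.6, 0.1) with
  σα0β0 = 0.05, στ0ε0 = 0.1; all 12 parameters within 2 Monte-Carlo SEs,
  pooled 95%-CI coverage in [85%, 99%].  The m ≪ n panel gives the GRM
  enough off-diagonal structure to separate K-linked from identity-linked
  components at this n; with m ≫ n the slope components decouple slowly
  and small-sample transfer between σ²α1 and στ1² appears.
- **Type-I error / uniformity**: 100 null replicates at n = 500, m = 300
  (with genetic and residual Y–C correlation present), exact binomial 95%
  band for rejections at 0.05, KS uniformity at 0.01, Fisher combination
  over 33 triples.
- **Power**: σ²α1 ∈ {0, 0.05, 0.10} at n = 500, 20 replicates per level,
  nondecreasing within one-sided Monte-Carlo tolerance (measured rates
  0.08 / 0.12 / 0.56).
- **RINT sensitivity**: 100 skewed-null replicates (target skewness 0.47)
  at n = 500; rejection count of the RINT analysis within the exact
  binomial 95% band.

**A known small-sample limitation the suite makes visible.**  At per-fit
n = 500 the full-vs-null LRT is anticonservative: measured rejection at
nominal 5% is ≈ 13% (n = 500) and ≈ 21% (n = 250), decaying roughly as
1/n.  The excess comes from null replicates in which the 12-parameter
full model reaches the near-singular region of the covariance cone and
harvests likelihood there; the PD margin truncates the most extreme
statistics (halving the mean excess of the LRT statistic) but most such
replicates still cross the 5% cutoff.  The effect is a property of the
unconstrained reaction-norm likelihood at small n, not of the optimizer —
the same fits match independent derivative-free maximization wherever an
interior optimum exists, and parameter estimates remain unbiased with
correct CI coverage.  At the subgroup sizes this model is used with in
practice (tens of thousands), the excess term is negligible.  The type-I
and RINT calibration tests therefore fail their binomial bands at desk
scale and are retained as honest red markers of the method's sample-size
requirement: per-subgroup n in the thousands is needed before the χ²
reference is trustworthy.

## Design choices and limitations

- PLINK1 binary and GCTA 3-file GRM are the supported interchange formats
  (hand-written codecs; both verified against hand-packed bytes and
  round-trips).  Missing dosages use an explicit sentinel and are only
  mean-imputed inside GRM construction, never at read time.
- The GRM divisor is the common SNP count m (GCTA default); a per-pair
  divisor is not implemented.  Allele frequencies are in-sample.
- The analysis scripts under `analysis/` are the command-line surface of
  the package; the library functions are the API.  No separate CLI binary
  is shipped.
- Meta-analysis of variance components is fixed-effect inverse-variance;
  the method is pluggable at the function level.
- One GRM per analysis group, subset per subgroup (recomputation per
  subgroup is a trivial variant at the call site).
- Known limitations: single-covariate models only (the multivariate
  extension raises the computational burden sharply); dense algebra caps
  practical per-fit n at a few thousand on one CPU — the subgroup +
  Fisher design exists precisely to make biobank-scale analysis feasible,
  at some cost in power; LRT calibration requires n of several hundred
  per subgroup; curve standard errors are delta-method approximations.
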