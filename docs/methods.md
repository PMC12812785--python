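# Methods

## The generating model

A twin pair's trajectory on two traits — P, a general psychopathology
factor score, and H, the child-rated home environment — is modelled as the
sum of three latent processes, one per biometric variance component
X ∈ {A, C, E}. Each component follows a lag-1 vector autoregression over
three measurement occasions (ages 9, 12, 16):

    x_{X,t+1} = B_X x_{X,t} + ζ_{X,t+1},

with a free 2×2 wave-1 covariance Σ_{X,1} and innovation covariances
ψ_{X,2}, ψ_{X,3}. Transition matrices are row = outcome trait,
column = predictor trait, traits ordered [P, H]. Co-twins share transition
matrices; their latent scores correlate r_A = 1 (MZ) / 0.5 (DZ), r_C = 1,
r_E = 0 at wave 1 and in every innovation. Because every cross-twin
covariance of component X is r_X times its within-twin counterpart, the
cross-twin 6×6 block of the implied 12×12 pair covariance is exactly r_X
times the within block, summed over components. The observed phenotype is
the component sum plus optional linear age and sex effects.

Assumptions worth stating plainly: Gaussian innovations (scores are
residualized and standardized, so normality is the working approximation);
occasions are categorical — three discrete waves, not continuous time; no
dominance, assortative mating, sibling interaction, rater bias or
sex-limitation structure; a single DZ group (no opposite-sex distinction in
the covariance model, though DZ co-twin sexes are drawn independently).

Component-level transmission (separate B_A, B_C, B_E) rather than a single
phenotypic transmission was chosen because it makes the %A/%C/%E
decomposition of every path well-defined and additive: the phenotypic lag-1
path matrix is B_ph = (Σ_X B_X Σ_{X,t}) Σ_t⁻¹ and component X contributes
the term B_X Σ_{X,t} Σ_t⁻¹ to it.

## Path decomposition and share targeting

For each stability and cross-lagged path, the three component contributions
sum exactly to the phenotypic coefficient. Percentages are
contribution/path when all contributions share the path's sign; with mixed
signs they are normalized by the sum of absolute contributions. The
absolute-value convention guarantees nonnegative rows summing to 100, at
the cost of interpretability when a component genuinely opposes the path —
such rows carry a `mixed_signs` flag.

`solve_shares` inverts this map: it shifts each component's lagged
coefficient B_X[to, from] so its contribution equals the target share times
the (held-fixed) phenotypic path. Because contributions are linear in B_X
with sensitivity M_X = Σ_{X,t} Σ_t⁻¹, one pass is exact; a target is
infeasible exactly when a component with zero variance on the predictor
trait is asked for a nonzero share.

## The synthetic cohort and what it does not emulate

Defaults mirror the emulated study design: 6,212 pairs, 34.4% MZ, 50.9%
female, ages 9.02 (SD 0.29), 11.31 (0.72), 16.32 (0.68); 10% per-wave MCAR
cell missingness and 50% wave-3 pair attrition (half the sample was not
assessed at 16). The home environment is emitted as two indicators, chaos
and discipline, built as H ± δ with Var(δ) chosen so they correlate at 0.3;
their mean reproduces H exactly, mirroring the equal-loading composite used
downstream. Optional continuous indicator items (item = λ·z(p) + noise)
support the CFA stage.

The generator does not emulate ordinal/Likert item response processes,
informant disagreement structure (each rater's model is generated and
analysed separately), non-normal tails, or MNAR missingness. Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to the many ways real questionnaire
data violate them.

## Estimation

All covariance-structure fits maximize the casewise (full-information)
Gaussian likelihood: rows grouped by missingness pattern once, each
objective evaluation then costs one small log-determinant/solve per
pattern. Means are fixed at pattern-pooled column means — the analysed
scores are residualized to mean zero, and on complete data this equals the
saturated ML means.

- *CLPM*: on complete data the lag-1 likelihood factorizes, so ML equals
  equation-wise least squares (closed form; also used per bootstrap draw).
  Under monotone wave dropout (e.g. pure wave-3 attrition) the
  factorization still holds and sequential regression on the available
  subsamples is exact ML. Only cell-level missingness requires the
  numerical optimizer (L-BFGS-B on a Cholesky parameterization,
  warm-started in the bootstrap). Model df = 4: the lag-2 covariance is the
  constrained moment Cov(y₃, y₁) = B₂₃ Cov(y₂, y₁).
- *Univariate ACE*: (a, c, e) enter as square roots, so variances are
  nonnegative without box constraints; fractions are reported relative to
  the fitted total. Submodels AE/CE/E are compared by naive LRT and AIC
  (no boundary-mixture correction, as is conventional in this literature).
- *Cross-lagged ACE*: 51 parameters (per component: chol Σ₁ 3, B₁₂ 4,
  B₂₃ 4, chol ψ₂ 3, chol ψ₃ 3) against the pooled MZ+DZ likelihood of the
  12-dimensional pair vector. Start values come from the linear moment
  identities W_A = 2(C_MZ − C_DZ), W_C = 2C_DZ − C_MZ, W_E = W − C_MZ
  (eigenvalue-clipped to the PSD cone, then block regression), which are
  already consistent, so the optimizer mostly polishes. Up to 4 jittered
  restarts; reported processes are rescaled post hoc so total phenotypic
  variance is 1 per trait per wave (path shares are invariant to this).
- *CFA*: uniquenesses on a log scale floored at 1e-6 (Heywood cases clamp
  and flag); identification by unit factor variance, sign by first
  loading ≥ 0. When the factor model fails to beat the zero-loading null at
  α = 0.001 the null solution is reported with a `degenerate` flag, because
  the single-factor likelihood has an identification ridge on noise data.
- *Bootstrap*: percentile, case-resampling at the independent-row level
  (selected singletons, or pairs for the ACE CIs); 1,000 draws default for
  CLPM paths, 500 for ACE fractions; deterministic given the seed; a >5%
  refit failure rate aborts.

## Recovery batteries and problem sizes

Estimator checks simulate at the design's own scale: 5,000 pairs (34% MZ)
for univariate ACE profiles, 10,000 singletons for CLPM paths, 20,000 pairs
for the biometric decomposition, 5,000 MZ pairs for the differences design,
200 replicates of n = 2,000 for bootstrap coverage. Single draws at these
sizes carry sampling SEs comparable to the recovery tolerances (SE(â²) ≈
0.025; the cross-lagged path's A-share SE ≈ 10 points at 20,000 pairs), so
tests and the acceptance script average fixed seed batteries of replicates
(10 univariate, 5 CLPM, 24 decomposition, 5 MZ-diff) and assert the
tolerance on the battery mean — a bias test at the stated n, with
battery-mean SE two to three times below tolerance.

Generating values not fully determined by the published estimates were
fixed once: shared-environment fractions for the univariate profiles
(parent p 0.15/0.08/0.12; twin p carries its ~40% nonshared share; home
environment C-dominant at 0.51/0.51/0.40), the non-dominant complements of
stability-path share targets (remainder split evenly), and CLPM nuisance
structure (autoregressions 0.70/0.40, wave-1 correlation 0.30, innovation
correlation 0.20).

## Known limitations

- The cross-lagged ACE decomposition of *cross-lagged* (as opposed to
  stability) paths is intrinsically noisy: the MZ/DZ contrast identifies
  the A/C split of a small coefficient, giving per-draw share SDs near 10
  percentage points even at 20,000 pairs. Single-study decompositions of
  weak paths should be read with wide error bars.
- Fit statistics under missing data are computed against the complete-case
  saturated covariance; with heavy attrition they describe the completers.
- The MCAR-plus-attrition missingness generator is the simplest
  MAR-compatible mechanism; FIML's MAR robustness beyond MCAR is not
  exercised by the test suite.
- The difference-score CLPM treats within-pair differences as independent
  across pairs (true in the generator; plausible, not guaranteed, in real
  cohorts).
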