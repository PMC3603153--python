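# Methods

## Model and estimation

`groupfa` fits a factor analysis model with one latent structure per
diagnostic group and a single diagonal noise covariance shared across
groups. For a subject in group `j` (of `M`), with `D` observed features
and `K` latent factors:

    x = mu_j + L_j f + u,   f ~ N(0, I_K),   u ~ N(0, Psi),

so the within-group marginal is `N(mu_j, L_j L_j' + Psi)`. The group
proportion vector `pi` is taken from the observed labels and is not
re-estimated during fitting: the labels are clinical diagnoses, treated
as informative rather than latent.

Estimation is EM.

- **E-step.** The posterior of `f` given `x` and group `j` is Gaussian
  with precision `R_j = L_j' Psi^-1 L_j + I`, mean
  `R_j^-1 L_j' Psi^-1 (x - mu_j)` and second moment
  `R_j^-1 + mean mean'`. Group responsibilities `h_ij` are either fixed
  to the diagnosis (supervised mode, the default) or recomputed from the
  current parameters as
  `h_ij ∝ pi_j N(x_i; mu_j, L_j L_j' + Psi)` (soft mode).
- **M-step.** The factor vector is augmented with a constant 1, which
  folds the group mean into an extra loading column; the augmented
  loadings solve one responsibility-weighted least-squares system per
  group, and the shared `Psi` is the responsibility-weighted average
  residual-times-data diagonal across all groups, computed with the new
  loadings. With hard responsibilities this is exactly the classical
  factor-analysis EM applied per group with a pooled noise update, and
  the observed-data log likelihood is non-decreasing; the supervised
  objective is the sum of assigned-group log densities, the soft
  objective the mixture marginal.

Both updates are evaluated in a numerically safe form: group densities
through Cholesky factorizations of `L_j L_j' + Psi`, responsibilities in
log space with log-sum-exp.

Soft reestimation of the proportions (column means of the soft
responsibility matrix under the fitted parameters) is exposed as a
diagnostic, separate from fitting: it shows how far the feature evidence
pulls the composition away from the labelled one.

## Identification: rotation and alignment

The likelihood is invariant under `L_j -> L_j H` for orthogonal `H`, and
under column sign flips and permutations. Two post-fit steps restore
comparability:

1. **Varimax** per group, maximizing the variance of squared loadings per
   factor. The implementation is the classical SVD-based iteration. Since
   that iteration can stall in a non-global stationary point, it is run
   from the identity plus four deterministic random orthogonal starts
   (seeded from the matrix shape only, so results are reproducible) and
   the best criterion wins; on K=2 problems this matches a 0.001-radian
   grid search over all planar rotations and reflections. Kaiser row
   normalization (rows scaled to unit communality before rotation,
   undone after) is the default; rows with zero communality are an
   error in that case. The returned rotation satisfies `output = L @ H`
   exactly because row scaling commutes with column rotation.
2. **Alignment** of each group's columns to a reference group (group 1
   by default): similarity is absolute Pearson correlation between
   loading columns — scale-free, and consistent with reporting
   correlations between whole loading matrices. The K×K assignment is
   solved exactly by the Hungarian algorithm; the matched sign is the
   sign of the raw correlation, with zero-correlation ties resolved to
   +1 and permutation ties to the lowest index. An exhaustive variant
   enumerates the full product space of per-group sign vectors and
   permutations (`2^(KM) (K!)^M` candidates, guarded to K ≤ 4, M ≤ 3)
   and serves as the optimality oracle; because the objective sums each
   group's similarity to the reference, the groups decouple and the two
   algorithms agree exactly.

Applying a (permutation, signs) entry jointly to loadings and scores
leaves the reconstruction `L S'` unchanged.

## Preprocessing

Features are divided by intracranial volume where absolute volumes are
supplied, then centered and scaled to unit variance using pooled
(all-subject) statistics — one global pass before any group modelling, so
between-group mean differences stay in the data. The standard deviation
uses the unbiased N−1 denominator; at cohort sizes in the hundreds the
choice is immaterial. Constant columns and missing values are rejected,
not imputed.

## Diagnostics

- **Scree / Kaiser.** Eigenvalues of the sample covariance of the
  standardized data, cumulative variance percentages, and the count of
  eigenvalues above 1.
- **KS normality of scores.** One-sample Kolmogorov–Smirnov against the
  *fixed* standard normal, because the model asserts `f ~ N(0, I)`. A
  Lilliefors-type test with estimated moments would answer a different
  question (normality of shape only); the fixed-null choice is the
  faithful model check and is stated here because either convention
  appears in applied reports.
- **ANOVA.** Classical one-way F per feature across groups, `(M-1, N-M)`
  degrees of freedom. An everywhere-constant feature is reported as
  F = 0, p = 1 by convention and logged.
- **Loading comparison.** The distance between aligned loading matrices
  is the pairwise Frobenius norm (aggregate: mean over unordered pairs);
  there is no single standard "distance between loading matrices", so
  the metric is named explicitly in the output. Correlations are Pearson
  correlations of the vectorized aligned matrices.
- **Score–covariate association.** Per-group OLS of the covariate on a
  factor score with Pearson r, for relating scores to external measures
  such as cognitive test results.

## Synthetic cohorts

The generator draws labels from the proportion vector (multinomial by
default; a fixed-size largest-remainder option exists for deterministic
fixtures), factor scores `N(0, I)`, and noise `N(0, Psi)`, and assembles
`x = mu_j + L_j f + u`. Identical seeds give identical cohorts. A draw
that leaves a group empty is retried up to 10 times, then fails.

The AD-like preset emulates a three-group dementia morphometry cohort:
15 unit-scale volume-ratio features (7 bilateral pairs plus a
brainstem/ventricle measure), proportions (75.96, 16.83, 7.21)%,
simple-structure loadings in which left/right homologues load on the same
factor (limbic, basal-ganglia, diencephalic), dominant loadings 0.8
(0.7 on the limbic factor in the patient groups), noise variances
0.30–0.45 (communalities near 0.6, total feature variance near 1), and
patient means shifted down 0.5–1 SD on the structures that atrophy —
strong enough to separate groups, mild enough that posterior
responsibilities stay non-binary. What it does **not** emulate:
segmentation error structure, site/scanner effects, age and sex
covariance, non-Gaussian tails, or correlated (non-diagonal) measurement
noise. Tests passing on these cohorts therefore validate the estimation
machinery, not the adequacy of the model for any real imaging dataset.

`make_recovery_spec` is the same cohort with equal group proportions,
used for parameter-recovery experiments so each group's loadings are
estimated from the same number of subjects.

## Numerical choices and problem sizes

- Convergence: relative change `|dLL| / (|LL| + 1) < 1e-6`, `max_iter`
  1000 by default.
- `Psi` is floored at 1e-6 to prevent Heywood-case singularities; floor
  events are counted and logged.
- Initialization: within-group means, pooled within-group residual
  variances for `Psi`, label proportions for `pi`, and seeded
  `N(0, 0.1^2)` loadings to break rotational symmetry. Only the loadings
  are random; the seed is mandatory in the CLI.
- Groups with fewer than two members are rejected before fitting.
- Monotonicity and invariance checks in the test suite run 50–100
  randomized instances at the study shape (D = 15, K = 3, M = 3,
  N = 100–300); the recovery loop uses 10 cohorts of N = 2000. These
  sizes give stable averages while keeping the default suite quick.

## Known limitations

- The recovery experiment's fitted per-group model covariance sits
  roughly 0.5–0.7 in Frobenius norm from the generating covariance at
  N = 2000 with balanced groups. This is the sampling floor, not an
  optimizer artifact: for D = 15 unit-variance features the sample
  covariance itself fluctuates by about
  `sqrt((tr C)^2 + ||C||_F^2) / sqrt(n)` ≈ 0.6 at n ≈ 667 per group,
  and the fitted covariance from all 2000 subjects pooled into a single
  group still shows ≈ 0.34. Loading-level recovery is much tighter
  (mean worst-entry deviation ≈ 0.09 balanced; ≈ 0.17 under the
  unbalanced AD-like proportions, where the smallest group has only
  ~144 subjects).
- Supervised mode treats diagnoses as exact; label noise propagates
  directly into the group structures.
- The unsupervised mixture (learned proportions, no labels), oblique
  rotations, Bayesian estimation and missing-data EM are out of scope.
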