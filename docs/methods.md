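# Methods

`cohortlasso` implements a biomarker–outcome association analysis for small
clinical cohorts in which the number of candidate predictors approaches the
number of patients, predictors are strongly inter-correlated, and some
measurements are missing because they fell outside an assay's calibrated
range. The pipeline has four stages: chained-equations imputation with a
Cohen's *d* audit, L1-penalized (lasso) regression fit by pathwise
coordinate descent, repeated cross-validation with an explicit robustness
screen, and a synthetic cohort generator that provides the test bed for all
of it.

## Imputation and its audit

Missing biomarker cells are filled by multiple imputation with chained
equations (MICE) restricted to biomarker columns. Outcome columns are never
imputed and never used as predictors, so no outcome information can leak
into the filled values and bias the downstream selection.

Each of the *m* imputations (default 15) starts from observed column means
and cycles `iterations` times (default 10) through the incomplete columns
in order of ascending missing count, ties broken by column order. Per
column, the observed values are regressed by least squares (with intercept)
on all other biomarkers at their current working values; missing cells are
redrawn as predicted mean plus Gaussian noise with SD equal to the
regression's residual SD (`sqrt(RSS / max(n − rank, 1))`). Drawing with
residual noise is proper imputation; the subsequent collapse of the *m*
tables by the cell-wise mean then yields a stable single table. The
iteration count is not critical — convergence is monitored as the maximum
absolute change of imputed cells per cycle and recorded on the result — and
ten cycles is ample for the 30-column problems this package targets. A
rank-deficient regression falls back to ridge-stabilized least squares
(penalty 1e−6) and is logged; imputed values are deliberately not clipped
to the observed range (out-of-range draws are logged at debug level).
Perfectly collinear predictors have zero residual SD, so their imputations
are exact.

The audit quantifies what imputation did to each biomarker's distribution:
Cohen's *d* between the observed-data summary (n₁, x̄₁, s₁) and the
completed-cohort summary (n₂, x̄₂, s₂),

    d = (x̄₁ − x̄₂) / s,   s = sqrt(((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2)),

with sample (n−1) SDs. Biomarkers without missing data carry no *d*. Under
MCAR the audit's |d| shrinks toward zero with the missing rate; under
low-censoring it measures the systematic downward correction the imputation
applies to the observed (upward-biased) means.

No Rubin's-rules pooling across the *m* imputations is performed: the
analysis deliberately collapses to one table so that the penalized fits
operate on a single complete dataset. The price is that between-imputation
variability is not propagated into the coefficient summaries; the repeated-
CV protocol below captures resampling variability only.

## The lasso solver

For k predictors standardized to mean 0 and SD 1 (population denominator n)
the solver minimizes the penalty (Lagrangian) form

    gaussian:  (1/(2n)) Σᵢ (yᵢ − β₀ − zᵢβ)² + λ Σⱼ |βⱼ|
    binomial:  (1/n) · [negative binomial log-likelihood] + λ Σⱼ |βⱼ|

with an unpenalized intercept; the binary outcome itself is not
standardized. Coefficients are always reported on both the standardized
scale (where the penalty acts) and the original predictor scale
(βʳᵃʷⱼ = βⱼ/scaleⱼ).

Gaussian fits use cyclic coordinate descent — the single-coordinate update
is the soft-threshold operator — warm-started along a decreasing,
log-spaced grid of 100 λ values from λ_max (the smallest penalty with an
all-zero solution, maxⱼ|⟨zⱼ, y−ȳ⟩|/n) down to 1e−4·λ_max. λ_max is inflated
by a relative 1e−12 so the null solution is exactly optimal at the grid top
regardless of floating-point summation order. Convergence is declared when
the largest single-parameter change in a sweep falls below `tol`
(default 1e−7), with a hard cap of 1e5 coordinate updates per λ. Exact
zeros are represented as literal zeros. When two predictors are perfectly
collinear the sweep order (ascending column index) decides which one
enters; this tie-break is unstable by construction and documented as such.

Binomial fits wrap the same coordinate solver in iteratively reweighted
least squares: working weights w = p(1−p) floored at 1e−5, working response
η + (y−p)/w, outer loop until the parameter change after a reweighting
falls below `tol`. When any fitted probability leaves (1e−5, 1−1e−5) the
fit is in the quasi-separation regime: the solution is flagged saturated
and the path is truncated there (remaining grid points keep the last
solution and carry the flag), mirroring how glmnet ends its λ sequence
early. The per-column curvatures are recomputed for every weighted
subproblem, so the same kernels serve full-data fits and row-subset fits
during cross-validation; fold fits reuse the full-data standardization
(rows of the standardized matrix are sliced, with no per-fold
re-standardization), keeping the λ grid shared across folds. The kernels
are compiled with numba; the repeated-CV protocol performs thousands of
path fits per outcome.

Solver correctness is established against independent oracles in the test
suite: closed-form soft-thresholding on orthonormal designs, the
Karush–Kuhn–Tucker stationarity conditions at every grid point, the
ordinary-least-squares limit as λ→0 (checked at min_ratio 1e−6, where the
residual penalty bias is negligible relative to the 1e−4 agreement bound),
scikit-learn's `Lasso` (identical objective) for the gaussian family and
statsmodels' L1-penalized `Logit` for the binomial family.

## Cross-validation and the robustness screen

One CV round partitions the cohort into k = 10 folds (sizes differing by at
most 1; stratified for binary outcomes so per-fold event counts differ from
proportionality by at most 1), fits the path on each training portion, and
averages the held-out deviance (MSE for gaussian, −2·mean log-likelihood
for binomial) per λ. The optimal λ is the strict minimizer — not the
one-standard-error rule — with ties resolved toward the larger λ, and the
minimization is restricted to the usable part of the full-data path (grid
points before saturation/truncation): beyond that point the binomial
solutions diverge, and cross-validating over them would select models that
do not properly exist. The round's reported model is the full-data refit at
the optimal λ, which is read off a single shared (deterministic) full-data
path for efficiency. Predictive performance of binary models is the
rank-based Mann–Whitney AUC of the refit's in-sample scores, so it varies
across rounds with the selected λ; a cross-validated AUC can be computed by
scoring held-out folds instead, but in-sample is the default reported
summary.

The robustness protocol runs two phases with disjoint seed streams spawned
from one root seed. Screening: `n_screen` = 50 independent CV rounds; if
any round selects the null model (all coefficients zero, equivalently
optimal λ = λ_max — operationalizing "no λ minimizing cross-validation
error") or hits convergence trouble, the association is declared not robust
and no coefficient table is produced. Convergence trouble means:
non-convergence or saturation of the full-data refit at the selected λ, a
training fold with constant outcome, or a cohort whose rarer outcome class
has fewer members than k (stratified splitting infeasible). Training-fold
fits saturating deep in the path do not count: 84-patient folds separate
more easily than the full cohort, and their tail behavior does not impugn
the reported refit. Recording: `n_record` = 100 fresh rounds; per biomarker
the mean, SD, min, max and median of the refit coefficients (both scales),
the selection frequency (fraction of rounds with a nonzero coefficient),
and the optimal-λ and AUC distributions are reported. Medians are computed
throughout but the mean is the headline summary, the two being close in
practice.

## The synthetic cohort generator

The generator defines the study conditions the package is tested under. It
draws biomarkers from a multivariate Gaussian on the log10 pg/mL scale,
attaches outcomes from a known sparse model on the standardized-predictor
scale, and then blanks cells.

- **Correlation**: default two exchangeable blocks of 15 biomarkers with
  within-block ρ = 0.6 and zero between blocks — a stylized rendering of
  strongly inter-correlated pro- and anti-inflammatory panels. Any PSD
  matrix can be supplied; validation names the offending eigenvalue
  otherwise.
- **Binary outcomes** are Bernoulli with logit-linear probability; the
  intercept is calibrated by bisection so the cohort-averaged event
  probability equals the target prevalence within 1e−4 (closed form when
  the linear predictor is constant). **Continuous outcomes** are Gaussian-
  linear with a configurable residual SD.
- **Missingness**: MCAR (independent cell-wise blanking at the column's
  rate) or censor-low (the lower rate-quantile of a column blanked — an
  exact count — mimicking values discarded below a detection limit).
  Censor-low shifts observed means upward relative to the truth, which is
  what the imputation audit should then partially correct. Outcomes are
  never missing.
- **Seeding**: one root seed; the three stages consume fixed child streams
  spawned from `numpy.random.SeedSequence`, so generation is
  bit-reproducible and each stage's draws are independent.

The named preset `csdh93` ships the structure of the motivating cohort: 93
patients, the 30-biomarker panel with its published observed log-means
(0.48–3.72), log-SDs (0.17–0.83) and per-biomarker missingness counts (0 to
28 of 93; 16 of 30 biomarkers complete), a binary recurrence outcome
(`rrr`) at 16/93 prevalence, and a continuous preoperative hematoma-volume
outcome (`volume`, mean 154.3 mL, SD 73.0 mL). The recurrence outcome's
generative coefficients are sparse standardized-scale values concentrated
on IL-5, CXCL8, IL-13, IFN-γ, CXCL10, CCL5 and VEGF (the biomarkers the
recurrence model reports), so the preset carries recoverable signal; the
volume outcome has all-zero coefficients, giving the protocol a built-in
null that should be rejected. These are the package's own emulation
choices: real patient-level data are not distributed with it.

What the generator does **not** emulate: skewed or heavy-tailed
concentration distributions (everything is Gaussian on the log scale),
missingness that depends on other biomarkers or on outcomes (only MCAR and
within-column censoring are available), measurement error, or any
longitudinal/imaging structure. Passing tests therefore demonstrate that
the machinery is correct and that the protocol behaves as designed under
Gaussian, sparse-truth conditions — not that any particular real-data
finding is reproducible. Because only 93 patients are drawn, the robustness
verdict on synthetic recurrence outcomes is itself realization-dependent:
some seeds fail the screen (e.g., when the binomial draw yields few
events), which is precisely the fragility the protocol is designed to
expose.

## Numerical and design choices

- Penalty-scale λ (Lagrangian form), not the equivalent constraint form;
  reported λ values are directly comparable to glmnet's.
- Grid defaults n_lambda = 100, min_ratio = 1e−4 (the n > k regime).
- Deviance stored per λ is the mean training deviance; held-out deviance
  uses the same definition on test folds.
- Summary SDs across rounds use ddof = 1, defined as 0 for a single round.
- Degenerate inputs fail loudly with named coordinates: zero-variance
  predictors, constant outcomes, non-numeric CSV cells, missing outcome
  values, duplicated columns.
- Rendered pipeline tables round coefficients and effect sizes to 2
  decimals, λ to 3, AUC to 2; full-precision CSVs are always written
  alongside.
- Test and demonstration problem sizes (round counts, cohort sizes,
  replicate counts) are chosen so the whole suite exercises every claim at
  desk scale; the protocol's scientific defaults (50/100 rounds, k = 10,
  m = 15) are unchanged wherever a verdict or summary is asserted.

## Known limitations

- Single-imputation collapse understates imputation uncertainty (see
  above); the audit quantifies location shifts only.
- The in-sample AUC is optimistic relative to a cross-validated AUC.
- No elastic-net mixing, adaptive/group penalties, or post-selection
  inference: selection is by cross-validation error alone and p-values for
  selected biomarkers are deliberately not computed.
- The stability protocol is the repeated-CV screen described above, not
  complementary-pairs stability selection with error control.
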