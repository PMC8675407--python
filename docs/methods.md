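# Methods

This note documents the models and procedures implemented in `megasite`, the
defaults chosen where the design was genuinely open, and what the synthetic
data do and do not establish about behavior on real data.

## The setting

A mega-analysis pools subject-level imaging-derived measurements
(region-of-interest or vertexwise thickness, area, volume) contributed by
many sites into one statistical model. Sites differ in scanner hardware,
acquisition protocol, and recruitment (e.g., some sites enrol only young
participants, others only elderly), so site membership enters the analysis
three ways: as a batch label for harmonization, as per-site columns in the
design matrix, and as the exchangeability/variance-group structure for
permutation inference. Generalization is sought to the actual population
sampled by these sites, not to a hypothetical population of sites, so
between-site variability is treated as nuisance structure to model or
remove, not as a random effect to integrate over.

## Synthetic data

`simdata` generates, per element v and subject j of site i,

    Y_jv = alpha + X_j beta_v + gamma_i + delta_i * eps_jv,
    eps_jv ~ Normal(0, sigma^2),

the location/scale batch model that ComBat assumes: each site shifts the
mean by `gamma_i` (measure units) and scales residual variability by
`delta_i > 0`. Covariates are drawn per site — truncated-normal age with
per-site bounds, Bernoulli sex/group with per-site probabilities — which is
the minimal structure needed to produce site-confounded covariate
distributions. QC metrics are drawn per hemisphere from good/bad Gaussians
(defaults: Euler number mean −40, SD 30 for good scans; −400, SD 150 for
bad; ~130k vertices), rounded to the nearest even integer capped at 2,
because a closed triangulated surface has an even Euler characteristic and
defects only lower it. Default effect sizes in examples are illustrative;
no empirical study fixes them.

Randomness uses one master seed spawning named substreams (cohort,
measures, qc), each keyed additionally by a stable per-subject index, so a
fixed seed is bit-reproducible and reordering subjects never changes the
values any subject receives.

What the generator does **not** emulate: spatial correlation between
elements, non-Gaussian measurement error, site-by-covariate interactions in
the outcome, longitudinal structure, or realistic cortical geometry.
Passing tests therefore establish algorithmic correctness and statistical
calibration under the stated generative model, not robustness to every
feature of real imaging data.

## Meshes

Icosahedral spheres are built by recursive 1-to-4 triangle subdivision with
edge midpoints projected to the unit sphere, giving V = 10·4^n + 2,
E = 30·4^n, F = 20·4^n. Midpoints are deduplicated by keying on the sorted
parent-edge index pair — never by hashing floating-point coordinates — so
vertex counts are exact at every depth. Subdivision appends midpoints after
the parent vertices, so a coarser mesh of the family is an exact vertex
prefix of any finer one; `downsample` verifies this nesting.

The Euler characteristic is computed literally as χ = V − E + F with E the
number of unique undirected edges: 2 for sphere topology, 0 for a torus
(χ = 2 − 2g), additive over disjoint components. (Informal accounts
sometimes describe χ as changing by ±1 per hole or cavity; standard
topology gives 2 per handle and 2 per enclosed cavity, and this package
implements only the unambiguous V − E + F.)

Downsampling assigns each source vertex to its geodesically nearest
destination vertex (on the unit sphere this equals the chordal nearest;
ties break to the lowest destination index for cross-platform
determinism). `kind="areal"` sums assigned values, conserving totals — the
correct rule for surface area; `kind="pointwise"` averages them — the
usual rule for thickness. An area-weighted average is a documented
alternative for thickness aggregation; the default here is the unweighted
mean. Optional pre-smoothing is Gaussian in great-circle distance,
truncated at 3σ, with FWHM configurable and 0 (off) by default, since no
standard kernel width exists.

## De-identification

`scrub_nifti` operates on raw bytes of single-file NIfTI-1 (`n+1` magic,
plain or gzip): it zeroes the 80-byte `descrip` and 16-byte `intent_name`
fields, drops all header extensions (rewriting `vox_offset` to 352 with a
zero extender), and copies the image bytes verbatim, recording SHA-256
checksums of the data stream before and after. The operation is
idempotent. NIfTI-2 and two-file pairs are refused with clear messages
rather than half-supported. `intent_name` is scrubbed even though it may
hold a harmless statistical-map label; cautious defaults win here. JSON
sidecars are scrubbed recursively against a case-insensitive regex
denylist (names, dates, birth, address, institution, operator, etc.)
shipped as an editable JSON resource. DICOM handling is out of scope:
conversion tools already strip DICOM headers, and voxel-level defacing is
deliberately excluded (it can degrade downstream measurements and is a
separate tool's job).

## Quality control

The QC score is r = χ/V per hemisphere, more negative meaning more
reconstruction defects; hemispheres combine by `min` (worst) by default,
`mean` optionally — the field has not settled this choice, so it is a
flag. ROC curves treat "fail" as the positive class with lower scores
indicating failure; thresholds sweep all midpoints between adjacent
distinct scores plus ±∞, so the trapezoid AUC equals the Mann–Whitney U
statistic normalized by n_pass·n_fail. The operating threshold maximizes
Youden's J = TPR − FPR, with ties broken toward the lower (less
exclusionary) threshold to preserve sample size. Sites without usable
manual labels inherit the pooled all-site threshold and are flagged.
Exclusion is strict (`ratio < threshold`), so a subject exactly at the
threshold is kept; visually flagged subjects are excluded regardless, with
reason "visual". Five-number summaries use Tukey hinges with 1.5·IQR
outlier flags.

## Harmonization (ComBat and random intercepts)

ComBat follows the original parametric empirical-Bayes formulation.
Standardization fits Y on batch indicators (constrained to weighted-mean
zero via the n_i/N-weighted grand intercept) plus retained covariates,
pooling the residual variance per element with divisor N. Per-batch
location (γ̂) and scale (δ̂²) of the standardized residuals are shrunk
across elements: normal prior on γ with method-of-moments (γ̄_i, τ_i²),
inverse-gamma prior on δ² with moments-matched shape/scale (λ_i, θ_i), and
the coupled posterior equations iterated to a 1e-4 absolute change cap
(100 iterations; non-convergence warns and keeps the last iterate).
Adjustment maps Z through (Z − γ*)/δ* and restores the standardization
fit, so covariate effects are retained. The implementation agrees with
the reference R implementation (`sva::ComBat`) to ~1e-6 on a three-batch
fixture; with shrinkage disabled the location step reduces exactly to
per-batch mean-centering of standardized residuals, and the whole
adjustment is exactly equivariant under affine rescaling of Y.

One caveat documented deliberately: covariate effects are preserved up to
scale-estimation noise, not to machine precision — dividing by δ̂* ≠ 1
perturbs refitted covariate coefficients by O(10⁻³–10⁻²) at typical sizes
even when the true δ is 1.

The random-intercept alternative removes, per element, a shrunken site
intercept: site means of covariate-adjusted residuals scaled by
λ_i = σ_b²/(σ_b² + σ_w²/n_i), with between/within components from one-way
method-of-moments. It is location-only; with no true between-site variance
the adjustment is bounded by the site-mean sampling noise (~σ/√n), which
is the attainable floor for any per-element shrinkage estimator. On
location-only batch effects its group-effect estimates correlate > 0.95
with ComBat's. Non-parametric ComBat, longitudinal/GAM/CovBat variants,
and reference-batch mode are out of scope; harmonization is off by
default, the modeling route being the primary analysis path.

## Design matrices

"Random" intercepts/slopes here mean explicit per-site columns, not
integrated-out variance components: a random intercept is one indicator
per site (and no global intercept); a random slope for v is site_i × v
with v centered within site (decorrelating slope from intercept columns);
a quadratic transform adds v² under the same fixed/random rule. Two-level
categoricals are coded as centered ±½ indicators for intercept
interpretability. The contrast for a random-slope interest term spans its
per-site columns with site-size weights by default (equal weights
optional), so the mega-model estimate is the corresponding weighted mean
of per-site OLS slopes. Rank deficiency raises an error naming the aliased
columns; a covariate constant within a site loses that site's slope column
with a warning. With no fixed slopes or intercept anywhere, the design is
block-diagonal by site and the mega-fit reproduces separate per-site OLS
fits exactly — the identity the reporting module exploits.

Global covariates (total surface area, mean thickness, intracranial
volume) support three strategies: proportion (divide), residualize, or
include as a model column; inclusion is generally preferred and proportion
least reliable. `dual_model_run` fits with and without the global under a
shared permutation schedule and corrects jointly across both model
families, since presenting two models doubles the opportunities for false
positives. A global nearly collinear with the interest contrast
(|r| > 0.99) warns but still produces results.

## Inference

The test statistic is the Aspin–Welch v (rank-1 contrasts) and its F-type
generalization G (multi-column), the formulation used in the permutation
literature for the general linear model: each variance group b gets weight
W_b = dfres_b / SSE_b (dfres_b the trace of the residual-forming matrix
over the group), the contrast is estimated by weighted least squares, its
variance assembled from C'(M'WM)⁻¹C, and a Welch-type correction Λ applied
for s > 1. With one variance group v and G reduce exactly to the classical
t and F. These formulas are adopted from the published statistic, not
derived here. Variance groups default to site; exchangeability blocks
default to scanner when present, else site (scanner granularity for the
blocks, site for the variance groups, and the two can be set
independently).

Permutation follows Freedman–Lane: nuisance columns (zero contrast weight)
are fitted, their residuals permuted within blocks, the nuisance fit
re-added, and the statistic recomputed under the full model. The identity
permutation is always first, and p = (1 + #{perm ≥ observed})/(1 + n_perm),
so p ≥ 1/(n_perm + 1) and the test is valid at finite n_perm. When the
number of within-block rearrangements (∏ n_b!) is at most 50,000,
exhaustive mode enumerates them and the p-value is the exact enumeration
probability; above the cap, sampling (with possible duplicates) is used.
t-type contrasts are two-sided via |v|; G is right-tailed. Tie comparisons
use a 1e-12 relative tolerance so mathematically identical rearrangements
count as ties despite floating-point noise.

FWER correction refers each observed statistic to the permutation
distribution of the maximum over all pooled tests — across elements and,
in joint mode, across families (measures × models × contrasts) sharing one
permutation schedule; mismatched schedules are refused. This is exact
under the permutation null regardless of dependence, hence never more
conservative than Bonferroni on correlated elements. BH FDR adjustment is
delegated to statsmodels. Spatial statistics (cluster extent/mass, TFCE),
sign-flipping, parametric random-field corrections, and permutation
accelerations are out of scope in this version; the permutation loop is
plain, with the element dimension vectorized.

Calibration was checked by simulation: with 2 sites of 20 subjects and a
1:16 residual variance ratio, 500 permutations and 1000 replicates, the
element-wise rejection rate at α = 0.05 was 0.053 and the 10-element joint
max-statistic FWER 0.051. (Replicate counts in the test suite are chosen
so the Monte-Carlo standard error is small relative to the asserted bands.)

## Reporting

Per-site breakdowns are separate OLS fits per site (computationally
lighter than refitting the mega-model, and identical to it when the model
has no fixed terms). The combined row is the inverse-variance-weighted
mean with a normal-approximation 95% interval (sample-size weighting
optional; interval construction is a convention choice, not estimated from
data). Sites with an inestimable contrast (e.g., one diagnostic group
absent) are flagged and excluded from the combined estimate. Exports are
TSV with −log₁₀ p columns, plus per-vertex map files when the elements are
mesh vertices.

## Degenerate inputs and numerical choices

- Zero vertex counts, non-positive scale effects, single batches,
  singleton batches, single-class ROC labels, zero-residual-dof variance
  groups, and rank-deficient designs all raise typed errors
  (`ConfigurationError`, `DataError`, `FormatError`, `EstimationError`).
- Least-squares fits use `numpy.linalg.lstsq`; batched weighted solves use
  stacked `numpy.linalg.solve`. Group SSEs are floored at 1e-300 to avoid
  division by zero in pathological all-zero elements.
- The test suite sizes simulations (tens of subjects per site, tens of
  elements, hundreds of permutations; 1000 replicates for the calibration
  check) so the full run completes in well under a minute while keeping
  Monte-Carlo error small relative to every asserted band.
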