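# Methods

This note documents the models, numerical conventions and design choices
behind `dysbiom`, in the spirit of a statistical-methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator emulates a two-group acute-ischemic-stroke cohort (infected /
non-infected within 7 days) with the statistical structure the downstream
analysis assumes.

**Composition.** Each sample's taxon profile is Dirichlet:
`x ~ Dirichlet(c ∘ f_g)`, where `c` is a cohort-level baseline concentration
vector and `f_g` a group-specific fold vector. Baselines are log-normal
(log-sd 1.0 for filler taxa; 0.5 for the planted panel taxa, since a
dysbiosis panel consists of consistently detectable organisms by
construction) and are block-rescaled so that pathogenic taxa hold ≈2% and
beneficial (SCFA-producer) taxa ≈12% of baseline concentration mass —
low-abundance opportunists, abundant commensals. Working on the
concentration scale keeps rows summing to 1 exactly, and the small
pathogenic share keeps the renormalisation distortion of a fold change
small: the infected/non-infected mean-abundance ratio of pathogenic taxa
stays within ~5% of the nominal fold (the test suite checks 10% at 2,000
samples per group). Defaults: 150 taxa, 10 pathogenic (fold 4), 10
beneficial (fold 0.25), total concentration mass 50 (controls
sample-to-sample overdispersion), multinomial read depth 10,000 for the
count table.

**Co-occurrence guild.** Real SCFA-producer communities co-vary; infection
is associated with a collapse of that cooperative structure. The generator
models this with a shared per-sample "guild activity" factor — a mean-one
log-normal (log-sd 0.6 by default, clipped at 0.8/beneficial-share)
multiplying the beneficial-taxon concentrations in non-infected samples
only, with the complementary mass absorbed by all other taxa so every
taxon's *expected* share is preserved exactly. This induces positive
pairwise correlation within the beneficial block in the non-infected group
and none in the infected group. At the default strength the induced
correlations sit mostly below the network module's |r| ≥ 0.6 edge threshold
(default cohorts give sparse-to-empty networks in both groups); the
directional contrast (more non-infected edges) emerges clearly at stronger
guild settings, which is how the network tests exercise it.

**Biomarkers.** Each serum biomarker is log-normal per group, parameterised
from a (median, Q1, Q3) summary: `mu = ln(median)` and `sigma` as the
least-squares fit to the two log-scale quartiles, which has the closed form
`(ln Q3 − ln Q1) / (2 z_0.75)` for any quartile asymmetry (when the printed
quartiles are asymmetric on the log scale, the model quartiles carry a
symmetric residual around them; the median is always matched exactly).
Log-normality is the natural choice here: all six analytes are strictly
positive and their clinical summaries are right-skewed. Default parameters
are the reported group medians/IQRs of NMDAR NR2B, butyrate, TMAO, RANKL,
iFABP and LPS; units are carried as opaque labels.

**Clinical covariates.** Age is normal per group (67.2 ± 10.4 infected,
57.8 ± 11.6 non-infected, floored at 18). Remaining covariates are only
loosely constrained by published summaries, so realistic forms were fixed
once: NIHSS is 4 + Poisson (λ 1.2 vs 0.6, giving group medians near 5 vs 4);
platelets are log-normal around 250,000/µL in both groups; lymphocytes are
log-normal with medians 1,400 vs 1,950/µL so the platelet-to-lymphocyte
ratio is elevated under infection; sex is Bernoulli (45.9% vs 69.8% male)
and dysphagia Bernoulli (29.7% vs 11.6%).

**Randomness.** One global seed feeds named substreams (labels, taxa,
abundance, counts, age, sex, each biomarker, …) via hashed seed sequences,
so adding a variable to the generator never perturbs existing draws, and
everything is bit-reproducible for a fixed seed.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: sequencing error, compositional zero-inflation
beyond what the Dirichlet implies, taxonomic correlation structure other
than the single beneficial guild, systematically *reduced alpha diversity*
in the infected group (the fold changes move composition more than
evenness), longitudinal dynamics, and any biomarker–microbiome coupling
beyond their shared dependence on the infection label. Because biomarker
group contrasts follow clean log-normals at the reported (large) effect
sizes, the default prognostic model separates the groups almost perfectly —
apparent and corrected AUC near 1 are a property of these synthetic
conditions, not a claim about patients.

## Dysbiosis indices

`MDI = log10[(1 + Σ a_path) / (1 + Σ a_ben)]` with unweighted sums over the
panel, exactly as printed in the clinical literature; on relative abundances
it is confined to ±log10(2). The SDI generalises this to
`log10[(ε + Σ w_i a_i) / (ε + Σ w_j a_j)]` with panel weights and a
configurable pseudocount (default ε = 1). The original SDI reference weights
derive from a healthy-control dataset that is not redistributable, so the
anchoring identity — unit weights and ε = 1 reduce SDI exactly to MDI — is
enforced by test, and panels either ship as JSON fixtures (Klebsiella,
Escherichia, Salmonella enriched; Faecalibacterium, Blautia, Agathobacter
depleted) or are derived from labelled data: per-taxon two-sided
Mann–Whitney, BH-FDR at α, sign of the group median difference, weight
|median difference| normalised to max 1. Panel taxa are matched to table
columns by exact identifier; no taxonomy-aware collapsing.

## Permutation inference

PERMANOVA uses the one-factor distance decomposition
(`SS_total = Σ_{i<j} d²_ij / n`, within-group sums weighted 1/n_g,
pseudo-F with k−1 and n−k degrees of freedom). When the number of distinct
label assignments is ≤ 10,000 the permutation distribution is enumerated
exactly and p is the exact tail proportion (ties count, so the observed
assignment guarantees p > 0); otherwise Monte-Carlo label permutation with
the add-one convention `p = (1 + #{F* ≥ F}) / (1 + n_perm)`. An all-identical
distance matrix is reported as statistic 0, p 1.

BETADISPER embeds the distance matrix by PCoA. Negative eigenvalues are
retained everywhere: ordination reports the full spectrum, and dispersion
distances use the standard correction in which imaginary-axis contributions
enter squared distances with a negative sign (clipped at zero). Each
sample's distance to its group centroid is computed with the spatial median
(Weiszfeld iteration on the positive-eigenvalue axes; the imaginary-axis
centroid is the group mean) or the mean centroid by flag; the test statistic
is the one-way ANOVA F on those distances, and the permutation scheme
shuffles group membership of the fixed distances (the residual-permutation
convention). Type-I error of both tests is verified against the binomial
99% band at α = 0.05 over 200 null replicates.

## Cohort statistics

The "as appropriate" test choice is codified: continuous variables get a
per-group Shapiro–Wilk screen at 0.05 — both groups normal → Student's t
(pooled variance by default, Welch by flag), otherwise Mann–Whitney;
categorical variables get chi-square without continuity correction unless
any expected cell is below 5 (then Fisher's exact, 2×2). Every result
records which test ran. Correlations are Spearman (mid-ranks) or Pearson;
the binary infection label is coded 0/1. BH-FDR is the step-up adjustment
with monotonicity enforcement. Rounded proportions use exact decimal
arithmetic with round-half-away-from-zero, matching clinical-table
conventions.

## Prognosis

Candidate predictors pass a univariate single-covariate logistic screen
(two-sided Wald p < 0.10 by default). The multivariable fit is
Newton–Raphson maximum likelihood on internally standardized predictors
(an exact affine reparameterisation, back-transformed afterwards, chosen
because assay units span five orders of magnitude and the bootstrap makes
~10⁵ small fits); complete separation — non-convergence, |standardized
coefficient| > 15, or a singular Hessian — triggers an automatic ridge
fallback with λ = 0.01 n on the standardized scale, flagged on the result.
In screening, a separated predictor counts as p = 0 and is selected.

Internal validation is the Harrell optimism bootstrap with the *entire*
procedure — screening included — repeated in each resample, so the optimism
estimate covers selection uncertainty; a test demonstrates that freezing the
full-data selection systematically underestimates optimism on noise.
Resamples missing an outcome class are redrawn (counted). The corrected AUC
is apparent − mean optimism; the CI is the 2.5/97.5 percentile interval of
the per-replicate corrected values (clamped to contain the point estimate).
AUC itself is the tie-aware rank estimator, identical to the trapezoidal
ROC area.

## Co-occurrence networks

Within a group, taxa present in ≥ 20% of samples are correlated pairwise
(Spearman by default; p from the t approximation, exact-1 correlations
floored at the smallest positive double), BH-FDR adjusted across all tested
pairs, with an edge when |r| ≥ 0.6 and adjusted p < 0.05. Constant taxa are
untestable and contribute no edges. Isolated nodes are excluded from node
counts by default (reported network sizes conventionally count connected
taxa), retainable by flag. All thresholds are recorded in the output.

## Pipeline and reproducibility

The orchestrator runs diversity → beta diversity → indices → cohort
statistics → prognosis → networks from either file inputs or a synthetic
spec (exactly one), derives per-stage seeds from the global seed by stage
name (toggling stages cannot shift other stages' draws), and writes a
manifest with package version, config hash and seed. Outputs contain no
timestamps; re-running a config is byte-identical. Simulation sizes used by
the test suite (e.g. 200 replicates for calibration checks, 200 bootstrap
resamples in the null-optimism study, 2,000 per group for fold-change
convergence) were chosen as the smallest sizes at which the binomial/Monte-
Carlo error bands stated in each test are meaningful.

## Known limitations

Single-factor PERMANOVA only (no strata or covariates); no
compositionality-aware correlation (SparCC-style) in the network module; no
UniFrac (no tree); the ridge fallback reports Wald intervals that ignore
penalisation bias; `derive_panel` assumes exactly two groups; the generator
draws biomarkers independently given the group label.
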