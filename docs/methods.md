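# Methods

## Model

Let subject *j* carry a latent profile *c ∈ {1…K}* with mixing
proportions π (the level-2 units). Each observed informant report
(self, parent — the level-1 units) contributes conditionally
independent ordinal subscale scores. The response model is an
adjacent-category (linear-by-linear) logit with equidistant category
scores:

P(x = k | c, i, s) ∝ exp(α[i,s,k] + β[c,i,s]·k),  k = 0…C−1,

with α[i,s,0] = 0. The category intercepts α are shared across classes
and give each (informant, scale) pair an arbitrary baseline score
distribution; the scalar location β shifts that distribution up or down
per class. This is the most parsimonious model that respects the ordinal
nature of the indicators while letting every class, informant and scale
differ in severity; a saturated per-category multinomial
parameterization (independent logit vector per class/informant/scale) is
available through `FitConfig(parameterization="multinomial")` for users
who want class-specific distribution *shapes* rather than shifts.

**Identifiability.** The adjacent-category block has one flat direction:
adding d to every class's β while subtracting d·k from α[k] changes no
probability. Fitted parameters are reported in the gauge where the
unweighted class mean of β is zero within each (informant, scale) block,
and the BIC's free-parameter count subtracts one per block accordingly:
p = (K−1) + I·S·(C−1 + K−1).

**Missing data.** Whole informant reports, or single scores, may be
absent; they contribute no factor to the likelihood, which is the
maximum-likelihood treatment when missingness is at random given the
observed data. With no observed scores a subject's posterior is the
prior π.

## Estimation

EM with multi-start. The E-step computes subject posteriors by Bayes
rule; the M-step updates π in closed form and maximizes each
(informant, scale) block's expected complete-data log-likelihood over
(α, β) jointly with L-BFGS using analytic gradients, warm-started at the
current values. Because each inner solve starts from the incumbent and
is monotone, the outer iteration is a generalized EM and the observed
log-likelihood never decreases (asserted in tests with slack 1e-9).
Category probabilities are floored at 1e-10 inside the likelihood to
avoid −∞ under degenerate categories.

Defaults: 20 random starts (Dirichlet(5) π, N(0,1) β, zero α), each run
for 30 burn-in EM iterations, the best continued to convergence
(relative log-likelihood change < 1e-8, max 500 iterations); ties break
toward the lowest start index. The short-run-then-refine schedule gives
the same optimum as running every start to convergence on the presets
while keeping K-range sweeps fast.

**Model selection.** BIC = −2·logL + p·ln(n) with n = number of
subjects, since the classes live at the subject level; the selection
table records logL, p and BIC per K so alternative sample-size
conventions can be audited.

**Class ordering.** Classes are reported in ascending expected
total-difficulties score (sum of the four difficulties-scale means,
averaged over informants). This makes labels and comparisons across
runs and seeds deterministic.

**Diagnostics.** Entropy R² = 1 − Σᵢ H(pᵢ)/(n·ln K) summarizes class
separation (1 = deterministic assignment).

## Three-step group analysis

Relating modal profile assignments directly to an external grouping
variable is biased whenever posteriors are non-degenerate. The package
implements the modal / maximum-likelihood variant of the three-step
correction:

1. fit the measurement model and keep per-subject posteriors;
2. assign each subject to the modal class (ties → lowest index) and
   estimate the classification error matrix
   D[c,w] = Σᵢ pᵢ(c)·1[wᵢ=w] / Σᵢ pᵢ(c), on the full estimation sample,
   held fixed across groups;
3. within each group, maximize Σᵢ log Σ_c θ[g,c]·D[c,wᵢ] over the
   simplex by EM (to elementwise change < 1e-12).

When D = I this reduces exactly to counting; a 1-D grid search verifies
the K=2 optimum in tests. The gender interaction applies the same
estimator per (group × gender) cell; cells under a configurable minimum
size (default 30) are flagged unstable, empty cells get no estimate.
Formatted reports show per-gender percentages only where the absolute
male/female difference reaches the reporting threshold (default 20
percentage points) and suppress groups below a minimum size (default
100), the conventional reporting rules for these tables. Standard
errors via subject-level nonparametric bootstrap (default 200
replicates) are optional — prevalence point estimates do not need them.

## Profile interpretation

Class means E[x | c,i,s] = Σ k·P(k | c,i,s) are banded against
user-supplied cutoffs per (informant, scale) and for the
total-difficulties sum. Boundaries are inclusive toward the less severe
band; the prosocial (strengths) scale is banded in reverse (low =
worse). The package ships only an *illustrative* cutoff file; published
norm cutoffs are configuration, not code.

Labels are a pure function of the band pattern: all-normal → "no
difficulties"; no abnormal mean → "borderline (affected domains)
difficulties"; otherwise "(abnormal domains) difficulties", collapsing
to "overall difficulties" at ≥4 affected domains. A domain counts as
affected when **either** informant's mean crosses the cutoff — a profile
where only the parent reports problems still carries the difficulty
label. This either-informant rule is deliberate (parent-only elevations
are clinically meaningful) and is the main judgment call in the
labeller; it is isolated in `label_profiles` and easily swapped.

Paired informant differences are tested per (cluster, scale) with
paired-sample t tests on subjects observed by both informants,
Bonferroni-corrected by the number of scales actually tested within the
cluster, at α = 0.01. The total-difficulties cross-tabulation bands each
subject's own informant-specific total (normal vs borderline/abnormal
merged) and estimates corrected profile prevalences within each
(setting, band) cell. The single-informant comparison refits the model
on one informant's records, selects K by BIC, and cross-classifies modal
assignments to detect profiles that merge when the second informant is
dropped (majority-overlap threshold 0.5).

## Synthetic data

The generator draws exactly from the model above — class from π, scores
from the adjacent-category model, whole informant records deleted
completely at random with the configured rate (a hook allows
covariate-dependent, still-MAR rates) — plus class-conditional group
covariates: each class has a categorical distribution over
(setting, diagnosis set, gender) cells, so the implied P(class | group)
follows by Bayes inversion and is exposed by `truth_report` and
`SimConfig.implied_class_given_setting` as recovery targets.

Presets fix the study conditions for the simulation experiments. All use
K = 3 severity-ordered classes (mixing 0.45/0.35/0.20), category
intercepts α_k = −0.11(k−5)² (a unimodal mid-scale baseline, sd ≈ 2
score points), class locations ±spread on difficulties scales (sign
reversed for prosocial), and a class-dependent setting/gender design:

| preset | location spread | separation |
|---|---|---|
| `well_separated` | 0.9 | entropy R² ≈ 0.99 |
| `moderate` | 0.40 | entropy R² ≈ 0.7 |
| `near_deterministic` | 1.6 | off-diagonal D < 0.01 |

The moderate spread was calibrated once so that the preset realizes the
entropy R² ≈ 0.7 regime in which classification-error correction
visibly matters; the well-separated preset is the parameter-recovery
condition. What the generator does **not** emulate: item-level
responses (only subscale totals), informant correlation beyond the
shared class (local dependence), non-MAR missingness, and population
non-representativeness. Passing tests therefore demonstrate correctness
of the machinery under the model's own assumptions, not robustness to
their violation on real questionnaire data.

## Problem sizes and numerical choices

Simulation-based tests use n = 2000 (recovery, missingness
robustness), n = 1000 × 10 replicates (BIC selection, 5 starts × 10
burn-in iterations per candidate), n = 1500 × 10 replicates (three-step
benchmark, scored under the true generating parameters so that
classification error — not estimation error — is the quantity under
test), and n = 300 with 20 single-start seeded fits for the EM ascent
property. The three-step benchmark's truth is the *empirical* class
distribution per group in each replicate, the estimand the corrected
estimator actually targets.

Degenerate inputs: empty datasets generate empty tables; K = 1 is a
saturated per-(informant, scale) multinomial and skips the three-step
stage; subjects lacking a group label or gender are excluded from the
corresponding group analysis and logged; a class with zero posterior
mass makes the error matrix undefined and raises.

## Known limitations

- The adjacent-category link and shared intercepts are one reasonable
  parameterization of "ordinal indicators"; other latent-class software
  may use cumulative or per-category links, so parameter estimates are
  not numerically comparable across implementations (class recovery and
  posteriors are).
- The EM M-step relies on a bounded inner optimizer; pathological
  blocks (all mass in one category) are handled by the probability
  floor, not by a dedicated boundary analysis.
- No significance tests accompany the step-3 prevalence estimates;
  bootstrap SEs are provided instead.
- The gender-interaction estimator treats cells independently; it does
  not pool or smooth small cells beyond flagging them.
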