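# sdqprofiles

Latent-profile analysis of multi-informant Strengths and Difficulties
Questionnaire (SDQ) subscale scores.

Screening adolescents for psychosocial problems typically uses a single
SDQ informant (the adolescent or a parent) and often only the total
difficulties score. Both choices throw information away: informants
disagree systematically, and a total score hides which *domains* are
affected. This package implements the alternative: treat the five
subscale scores from both informants as ordinal indicators of a latent
subject-level profile, estimate the profiles with a two-level finite
mixture model, and relate profile membership to external groups (care
setting, diagnosis category, gender) with the bias-adjusted three-step
estimator. It is aimed at researchers in youth mental-health
epidemiology and psychometrics who want a tested, scriptable version of
this workflow, plus a synthetic-data generator for method evaluation.

## The model

Subjects `j` belong to one of `K` latent profiles with mixing
proportions `π`. Conditional on the profile `c`, each observed informant
report (`i` = self, parent; level 1, nested in the subject at level 2)
contributes independent ordinal subscale scores `x ∈ {0, …, C−1}` from an
adjacent-category (linear-by-linear) logit:

```
P(x = k | c, i, s)  ∝  exp( α[i,s,k] + β[c,i,s] · k )
```

with category intercepts `α` shared across classes and a scalar location
`β` per (class, informant, scale). Missing reports and missing single
scores drop out of the likelihood (missing at random at the informant
level). Estimation is multi-start EM; the number of profiles is chosen
by the smallest BIC (`−2·logL + p·ln n`, `n` = subjects) over a range of
candidate `K`. Posterior profile probabilities score new cases from any
subset of observed scores.

The third analysis step relates profiles to groups: subjects are
assigned to their modal profile, the classification error matrix
`D[c,w] = P(assigned w | true c)` is estimated from the posteriors, and
the profile distribution `θ_g` within each group is recovered by maximum
likelihood, undoing the assignment error. Profiles are interpreted by
banding their class-mean scores as normal / borderline / abnormal
against user-supplied cutoffs, which yields automatic labels such as
"borderline hyperactivity difficulties".

## Worked example

```python
import numpy as np
from sdqprofiles import preset, generate, select_model, FitConfig, posterior
from sdqprofiles.records import to_score_array
from sdqprofiles.io import example_cutoff_config
from sdqprofiles.profiling import profile_summary

config = preset("well_separated", n_subjects=1000, seed=3)
data = generate(config)
X = to_score_array(data.subjects, config.spec)
fit, table = select_model(X, range(1, 5), config.spec,
                          FitConfig(n_starts=5, start_iters=10, seed=3))
print(table.to_string(index=False))
print(f"selected K = {fit.params.K}")

summary = profile_summary(fit.params, example_cutoff_config())
for c in sorted(summary["class"].unique()):
    row = summary[summary["class"] == c].iloc[0]
    print(f"class {c}: {row['label']!r}, prevalence {row['prevalence']:.3f}")

new_case = np.full((2, 5), -1)
new_case[0, :] = [9, 7, 7, 8, 2]   # self-report only
post = posterior(new_case, fit.params)
print("profile probabilities:", np.round(post.probabilities, 3))
```

prints

```
 K        loglik  n_free_params          bic error
 1 -23512.548965            100 47715.873458
 2 -20867.025676            111 42500.812189
 3 -19873.573197            122 40589.892538
 4 -19864.042653            133 40646.816759
selected K = 3
class 0: 'no difficulties', prevalence 0.453
class 1: 'emotional difficulties', prevalence 0.362
class 2: 'overall difficulties', prevalence 0.185
profile probabilities: [0.    0.018 0.982]
```

The BIC correctly recovers the three classes the generator planted
(true mixing 0.45/0.35/0.20); the new case — a self-report with high
difficulties scores and low prosocial score, parent report absent —
lands in the most severe profile with probability 0.98. Labels come
from the *illustrative* cutoff file; real analyses must supply
published norm cutoffs (`examples/cutoffs_example.yaml` shows the
format).

The same workflow is available from a shell:

```sh
sdqprofiles simulate --preset moderate --n-subjects 2000 --seed 1 --out sim/
sdqprofiles pipeline --subjects sim/subjects.csv --records sim/records.csv \
    --cutoffs examples/cutoffs_example.yaml --seed 1 --out run/
sdqprofiles score --model run/model.json --subjects new_subjects.csv \
    --records new_records.csv --out scores.csv
```

## Layout

- `sdqprofiles.records` — data containers (subjects, informant records).
- `sdqprofiles.mixture` — response model, likelihood, EM, BIC selection,
  posterior scoring, model serialization.
- `sdqprofiles.synthetic` — generator for two-level ordinal data with
  known ground truth; presets at three separation levels.
- `sdqprofiles.three_step` — modal assignment, classification error
  matrix, bias-adjusted group distributions, gender-interaction report.
- `sdqprofiles.profiling` — cutoff banding, profile labels, paired
  informant tests, total-difficulties cross-tabulation,
  single-informant comparison.
- `sdqprofiles.io` / `sdqprofiles.pipeline` / `sdqprofiles.cli` — CSV
  interchange, run configuration, end-to-end pipeline, CLI.

See `docs/methods.md` for the statistical details and design choices.
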