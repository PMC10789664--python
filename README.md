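# commrep

Analysis of non-vocal signal repertoires in immature orangutans: do young
Bornean and Sumatran orangutans living in the wild and in zoos use
different numbers — and different compositions — of gestures, body signals
and facial expressions, and does that depend on whom they signal to
(their mother versus peers and other conspecifics)?

The package is a reusable, tested implementation of that comparative
pipeline for researchers in primate communication and behavioural
biostatistics. It takes per-communicative-act interaction records
(signaller attributes, partner class, signal type, presumed social goal)
and produces:

1. **Customary repertoires** — an individual enters the analysis for a
   partner scope only with > 30 signal instances in that scope, and a
   signal type counts as customary only when used ≥ 2 times
   (`commrep.repertoires`).
2. **Repertoire overlap** — dyadic Dice similarity
   `D_C = 2·C_AB / (R_A + R_B)` between individuals, with
   matrix-permutation tests (labels permuted jointly over rows and
   columns, N = 1000, decision thresholds P ≤ 0.025 / P ≥ 0.975) for
   within- versus between-setting overlap per species and scope
   (`commrep.similarity`).
3. **Poisson mixed models** — repertoire size and social-goal diversity
   modelled as `y ~ Poisson(exp(Xβ + b_group))`, with age, age², research
   setting and species as test predictors, sex and log-z-transformed
   observation effort as controls, and a Gaussian random intercept per
   group; maximum likelihood via Laplace / adaptive Gauss–Hermite
   quadrature, full-vs-null and single-term-deletion likelihood-ratio
   tests, plus VIF, overdispersion, case-wise-deletion stability and
   Cohen's-kappa diagnostics (`commrep.glmm`, `commrep.diagnostics`).
4. **Synthetic data** — a generator that emulates the study design (two
   species × two settings, ~41 signal types, 7 goals, effort 32–776
   instances per scope, setting/species effects on other-directed but not
   mother-directed repertoires, shared within-setting signal cores) with
   known ground truth for calibration and recovery studies
   (`commrep.synthetic`).

## Worked example

```python
from commrep import (
    SyntheticConfig, generate_dataset, profile_individuals,
    build_repertoires, build_dice_matrix, matrix_permutation_test,
    ModelSpec, build_model_frame, fit_poisson_glmm, lrt,
)

records, population, truth = generate_dataset(SyntheticConfig(), seed=1)
profiles = profile_individuals(records)
reps = build_repertoires(records, profiles, scope="other")

settings = {p.individual_id: p.setting for p in profiles}
bornean = [r for r in reps
           if next(p for p in profiles
                   if p.individual_id == r.individual_id).species == "bornean"]
matrix = build_dice_matrix(bornean, settings)
perm = matrix_permutation_test(matrix, "within_vs_between", seed=1)
print(f"within - between Dice = {perm.observed_stat:.3f}, "
      f"p = {perm.p_value:.4f} ({perm.decision})")

spec = ModelSpec(response="repertoire_size", scope="other")
data = build_model_frame(reps, profiles, spec)
full = fit_poisson_glmm(spec, data)
null = fit_poisson_glmm(spec.null_spec(), data, se=False)
test = lrt(full, null)
print(f"full vs null: chi2_{test.df} = {test.chi_square:.3f}, "
      f"P = {test.p_value:.3f}")
print(f"setting (wild) = {full.coef('setting_wild'):+.3f} "
      f"± {full.se('setting_wild'):.3f}")
```

Output:

```
within - between Dice = 0.389, p = 0.0010 (significant_high)
full vs null: chi2_4 = 18.352, P = 0.001
setting (wild) = -0.445 ± 0.172
```

Same-setting dyads overlap far more than cross-setting dyads (the
permutation p is at its floor of 1/1001), and other-directed repertoires
are significantly smaller in the wild on the log scale — the two headline
contrasts the pipeline is built to measure.

The same analysis runs from the shell:

```sh
commrep run --simulate-default --seed 1 -o out/
cat out/summary.txt
```

or stage by stage (`commrep simulate / validate / profile / repertoires /
inventory / dice / permtest / glmm`). Real record tables are ingested as
CSV with the documented column schema; `read_records(path, column_map=...)`
adapts foreign column names.

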