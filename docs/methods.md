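# Methods

## Data model and filters

The unit of observation is one communicative act: an immature signaller
with fixed attributes (species ∈ {bornean, sumatran}, setting ∈ {wild,
captive}, group = zoo or field site, sex, one age for the study period)
directs one non-vocal signal type at one partner class (mother, peer, or
older non-mother conspecific) with a presumed social goal (seven
categories). "Other" is always the derived union peer ∪ older, never
stored, so follow-up analyses can split it without re-ingesting data. If
an individual appears with several ages, the mean is used and a warning
emitted.

Two conservative filters define the *customary repertoire* per
(individual, partner scope):

* eligibility — strictly more than `min_interactions = 30` signal
  instances in the scope (an individual can be eligible in one scope and
  not another);
* customary use — a signal type (and, by the same rule, a social goal)
  must occur at least `min_uses = 2` times in the scope. The
  goal threshold is configurable separately (`goal_min_uses = 1` counts
  every observed goal) because the convention for goals is genuinely
  open; applying the same ≥ 2 rule as for signal types is the default for
  internal consistency.

Population inventories are unions of *filtered* individual repertoires
per (setting × species × scope) cell; an unfiltered variant
(`raw_inventory_counts`) counts every observed type for comparison.
Raising either threshold can only shrink repertoires and inventories
(tested as a monotonicity property).

## Dice similarity and matrix-permutation inference

Repertoire overlap between individuals A and B is the Dice coefficient
`D_C = 2·C_AB / (R_A + R_B)` ∈ [0, 1], undefined when both repertoires
are empty. Matrices are built per species × scope only (no cross-species
dyads), with zoos pooled within species.

Because each individual contributes to n−1 dyads, pairwise values are
non-independent row- and column-wise. The null distribution is therefore
built by permuting the per-individual setting labels — equivalently,
jointly permuting rows and columns of the fixed similarity matrix — which
preserves the dyadic dependence structure and the group sizes. This
label-permutation scheme is the core interpretive choice of the module;
an exact-enumeration test over all C(n, n_captive) assignments serves as
the internal referee for small n.

Two contrast statistics are supported: mean(within-setting dyads, pooled)
− mean(between-setting dyads), and mean(captive-captive) −
mean(wild-wild). The Monte-Carlo p value is the upper-tail position with
add-one correction, p = (#{null ≥ observed} + 1)/(n_perm + 1): ties count
as at least as extreme (conservative) and p is never 0 — at the default
n_perm = 1000 a p of 1/1001 means no null draw reached the observed
statistic. The raw proportion and the lower-tail position are also
reported, since the contrast need not be symmetric around zero; decisions
use the asymmetric thresholds p ≤ 0.025 (significantly high) and
p ≥ 0.975 (significantly low), i.e. 2.5% per tail. Under an exchangeable
null the two-tailed decision rate is ≈ 5% (slightly above, 5.09%, from
the discreteness of the add-one rule; measured within ±1.5% in the
calibration test).

## Poisson mixed models

Repertoire size and goal diversity are counts, modelled as

    y_i | b_g ~ Poisson(exp(x_i'β + b_g)),   b_g ~ N(0, σ²),

with test predictors age, age², setting (wild vs captive reference) and
species (Sumatran vs Bornean reference), controls sex and observation
effort (log, then z-scored with the n−1 denominator on the analysis
subset), and a random intercept per group. age² is the square of raw age
by default; a centring flag exists because centring changes the
age/age² collinearity (VIF is computed from the main effects only, so
the default does not affect the reported collinearity check).

Estimation is maximum likelihood (not REML-like), so likelihood-ratio
tests on fixed effects are valid. The per-group marginal likelihood is a
1-D integral handled by the Laplace approximation (default) or k-point
adaptive Gauss–Hermite quadrature (`estimation="agq:k"`; k = 1 is exactly
Laplace). The inner mode solves S_g − e^b T_g − b/σ² = 0 by damped
Newton, vectorised over groups (the objective is strictly concave in b).
The outer optimiser is L-BFGS-B on (β, log σ) with starting values from
the plain Poisson GLM and σ₀ = 0.5; σ is bounded below at 1e−6, and fits
with σ̂ < 1e−3 are flagged singular and reported with variance 0.
Convergence tolerances: ftol 1e−12, gtol 1e−8. Standard errors are
observed-information Wald SEs for the fixed effects with σ at its MLE
(the usual mixed-model convention), from central finite differences.
On reference data the fit agrees with lme4's `glmer` to ~1e−5 in
log-likelihood, σ and coefficients (cross-checked in the test suite).

Inference: the combined effect of the four test predictors is the
full-vs-null LRT (null keeps controls + random intercept; df = 4 by
construction), and per-term tests are single-term-deletion LRTs (df = 1).
Diagnostics: dispersion = Σ(Pearson residual²)/(n − p_fixed − 1), using
conditional fitted values, with ≈ 1 expected for a well-specified model
(the residual-df convention is configurable in principle but this is the
one implemented); VIF_j = 1/(1 − R²_j) over the main effects; stability
by leave-one-group-out refits reporting per-coefficient ranges and sign
flips; Cohen's κ = (p_o − p_e)/(1 − p_e) as a standalone coding
reliability statistic.

A caveat the calibration study makes explicit: setting and species are
group-level covariates. With only a handful of groups (6–7, as in
field-plus-zoo designs of this kind) the χ² reference for their LRTs is
anti-conservative — a property of the method (lme4 behaves identically),
not of this implementation. The LRT calibration test therefore runs in a
40-group regime where the χ² reference is valid; results from few-group
designs should lean on the permutation layer and treat group-level LRT p
values with caution.

## Synthetic generator

The generator emulates the study conditions with known ground truth; its
defaults are the study-like design: 13 Bornean (8 wild at one field site,
5 captive across three zoos) and 14 Sumatran immatures (7 wild, 7 captive
across two zoos), a 41-type global inventory, 7 goals, ages uniform on
[1, 9] years, and per-scope effort uniform on [32, 776] instances with a
10% chance of a sub-threshold draw (5–30) to exercise the eligibility
filter.

Latent structure per individual:

* other-directed repertoire size ~ Poisson(μ), log μ = log 8 +
  0.42·captive + 0.52·sumatran + b_group, σ_group = 0.15 — the effect
  magnitudes mirror the printed study contrasts; mother-directed sizes
  use a base of 14 types with *no* setting or species effect, so
  wild-captive contrasts arise only beyond the mother–offspring bond;
* composition: each (species × setting × scope) cell owns an ordered
  "setting core" sampled from the global inventory with Zipf weights
  (common types enter every core, giving natural partial between-setting
  overlap); an individual takes the commonest min(k, core size) core
  types plus individually private periphery types. The
  `core_fraction` parameter scales the core size and hence the
  within-minus-between Dice gap monotonically (0 = exchangeable
  composition). With `core_fraction = 1` and deterministic sizes
  (`size_poisson=False`) all within-setting repertoires coincide and the
  within-setting Dice is exactly 1; with Poisson sizes the repertoires
  are nested prefixes and the expectation is slightly below 1;
* goals: each of the 7 categories is available to an individual × scope
  with probability `p_goal = 0.8`, identically across settings, so goal
  diversity varies between individuals but carries no setting effect;
* records: per partner class, exactly the profiled number of instances
  is drawn multinomially from the latent repertoire with Zipf-skewed
  frequencies (exponent 1), so rare types occur once and the ≥ 2 filter
  is non-trivial; other-directed effort is split peer/older binomially
  (p = 0.5).

`null_scenario` zeroes the setting/species effects and the core
structure, giving a fully exchangeable null for type-I-error studies.
`simulate_glmm_counts` bypasses the record layer and draws counts
directly from the Poisson random-intercept model (group-level setting and
species, n = 200, 10 groups by default) for parameter-recovery and
coverage studies where the estimand must equal the generator's β exactly.
One integer seed governs everything; per-cell and per-individual
sub-streams are derived deterministically, so edits to one part of the
configuration leave unrelated draws unchanged.

What the generator does *not* emulate: temporal sequencing and
persistence of interactions, partner-identity networks within groups,
age-dependent repertoire growth (age effects are absent by default, as
in the study's findings), observation-effort imbalance between partner
classes, and ethogram-level semantics of signal types. Passing
calibration and recovery tests therefore shows the statistical machinery
is correct under the assumed data-generating process, not that the
process captures every feature of real field data.

## Problem sizes and numerical choices

The calibration and recovery studies run at deliberately chosen scales:
permutation type-I error over 1000 datasets of 12 individuals
(6 wild / 6 captive, effort 40–120, n_perm = 1000); LRT uniformity over
150 datasets of 120 individuals in 40 small groups with effort 300–776
(high enough that the customary-use filter recovers the latent Poisson
sizes, making the Poisson likelihood exact for the response); recovery
and coverage over 200 replicates of the direct GLMM simulation at the
default effect sizes, with 240 observations in 80 small groups — again
because nominal Wald coverage for group-level coefficients is an
asymptotic claim in the number of random-effect levels. Monte-Carlo checks use binomial error bounds;
exact-vs-MC agreement is verified on every split of matrices up to 8
individuals. Ties in permutation statistics always count as at least as
extreme. Degenerate inputs (both-empty repertoires, one-setting label
vectors, zero-variance effort, rank-deficient VIF designs, < 2 groups)
raise informative errors rather than returning silently.

## Known limitations

* The permutation unit is the individual's setting label; alternative
  schemes (e.g. permuting raw repertoires across individuals) would test
  subtly different nulls and are not implemented.
* Wald SEs condition on σ̂; profile-likelihood intervals are not
  provided (LRTs are the primary inference, as in the analysed design).
* Group-level fixed-effect LRTs are anti-conservative with few groups
  (see above); the package reports them unadjusted.
* The fitter supports exactly one random intercept — the design analysed
  here — not crossed or nested random effects or random slopes, and no
  zero-inflation or negative-binomial response.
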