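# Methods

## Model

The 2-HT lineup identification model is a joint multinomial processing
tree over two independent multinomials: the three response categories of
culprit-present lineups and the three of culprit-absent lineups. Four
latent probabilities — presence detection *dP*, absence detection *dA*,
biased suspect selection *b*, guessing-based selection *g* — generate the
category probabilities given in the README. The `1/k` and `(k−1)/k`
branch weights (lineup size *k*) are structural constants of the design,
formed as exact rationals; *k* may differ across conditions within one
model, although every bundled study uses a single lineup size (5 for the
instruction study with five-person lineups, 6 otherwise).

A *model spec* binds each of the 4 × (number of conditions) parameter
slots to a named free parameter (shared names impose equality
restrictions) or to a constant in [0, 1]. Fixing `dA = 0` yields the
one-high-threshold variant. A spec with one free parameter per slot is
saturated: as many free parameters as independent categories and zero
degrees of freedom. Degrees of freedom are counted as 2 independent
categories per tree with a positive total (3 categories minus the sum
constraint) minus the number of free parameters; an empty tree
contributes no categories. Nestedness of two specs is verified
structurally: a restricted spec must assign a single value to every
equivalence class of the general spec's binding, and must keep the
general spec's fixed constants.

Several of the bundled data sets reconstruct the culprit-absent
suspect/filler split from a pooled false-identification count (total
divided by lineup size, rounded half up — the half-up direction is forced
by the published reconstructed cells). Degrees of freedom are computed
from the full 2 × 3 structure regardless, matching the published df
accounting; the ΔG² tests are unaffected by this choice because the
reconstruction is common to both models of each pair. A `strict_df`
switch subtracts one category per reconstructed culprit-absent tree for
sensitivity analysis.

## Estimation

Parameters are estimated by maximum likelihood under the
product-multinomial likelihood, equivalently by minimising

G² = 2 Σⱼ Oⱼ ln(Oⱼ / Eⱼ),

summed over all categories of all trees (terms with Oⱼ = 0 vanish; Oⱼ > 0
with Eⱼ = 0 yields an infinite statistic, reported as a non-fit). The
optimiser is the classic EM scheme for MPT models: the E-step distributes
each observed category count across the root-to-leaf branches ending in
that category in proportion to the branch probabilities, and the M-step
updates each free parameter as expected successes over expected trials
aggregated across every branch that contains it, with the structural
`1/k` weights held constant. Each fit uses 10 uniform-random starting
vectors plus one heuristic start (0.5 for detection parameters, 0.1 for
*b* and *dA*-style rarity, 0.5 for *g*); the best solution wins, with
first-found winning ties within 1e−9 of G². EM iterates until the
log-likelihood improves by less than 1e−10 (default) or 100,000
iterations, and non-convergence is flagged on the result rather than
silently ignored. Starts ending more than 1e−3 above the best G² raise a
multimodality warning; none of the bundled fits triggers it.

Because EM converges linearly and slows near flat optima, the final
solution is polished by an L-BFGS-B run on logit-transformed parameters
with the analytic score (chain-ruled through the logistic map). The same
quasi-Newton route doubles as an independent cross-check: the absolute
G² gap between EM and the optimiser is recorded in the diagnostics and is
below 1e−4 on every bundled fit. EM keeps iterates in the open unit
hypercube (clipped at 1e−12), so boundary solutions such as dA → 0 are
reported as values indistinguishable from the boundary and flagged
(`boundary=true` within 1e−4 of 0 or 1).

The fit statistic is referred to the upper tail of χ²(df); a saturated
model (df = 0) is given the degenerate reference: p = 1 when G² ≈ 0 and
p = 0 otherwise.

Standard errors are square roots of the diagonal of the inverse observed
Fisher information — the negative Hessian of the multinomial
log-likelihood kernel in the free parameters, obtained by central finite
differences of the analytic score with step 1e−4. The category
probabilities are polynomials in the parameters, so differentiation at a
boundary estimate is well defined; boundary SEs are reported but flagged,
since their usual Wald interpretation does not hold there. Whether the
published tables used observed or expected information is unknowable from
the printed values alone; the two coincide as the model fit improves, and
the observed-information values reproduce every printed SE within the
0.02 reproduction tolerance. A singular information matrix produces
undefined SEs plus an identifiability warning, never fabricated numbers.

Local identifiability is checked as the rank (SVD, relative tolerance) of
the numerical Jacobian of all independent category probabilities with
respect to the free parameters, with boundary estimates perturbed inward
by 1e−3 before differentiation.

Nested models are compared by ΔG² = G²_restricted − G²_general on
Δdf = df_restricted − df_general against χ²(Δdf). Negative ΔG² beyond
−1e−6 (impossible at true optima) raises a convergence warning before
being clipped to zero; Δdf ≤ 0 or a structural nesting failure is refused
outright.

## Bundled data

The eight fixtures transcribe the published frequency tables verbatim,
with the reconstruction conventions stated in each fixture's docstring
(suspect/filler splits by the 1/k rule; equal division of unreported
per-condition sample sizes; Wetmore's two designated innocent suspects
aggregated; the wildcard response scored as a lineup rejection). Each
fixture carries the comparison-standard spec used as the baseline for the
published hypothesis tests, one restricted spec per published ΔG² test,
and the published values themselves so the `reproduce-paper` report can
mark each reproduced quantity pass/fail (G² and ΔG² within 0.05,
estimates within 0.01 of the printed 2-dp values, SEs within 0.02 given
the information-matrix ambiguity above).

One transcription note: the instruction study with three conditions
reports culprit-present totals of 166/167/164 although the source text
describes equal division of the sample into six cells; the discrepancy is
residual rounding in the source's own proportions, and the printed
integers are stored as-is.

## Simulation

`sample_dataset` draws each tree's counts from a multinomial at the
model-implied category probabilities. Randomness follows a per-replicate
stream contract — replicate *r* of a study seeded with *s* always uses
`default_rng([s, r])` — so results are independent of execution order.
`recovery_study` reports per-parameter bias and RMSE across replicates,
counting (not discarding) boundary replicates and excluding only
non-converged fits. Simulation fits default to 2 random restarts plus
the heuristic start and skip the quasi-Newton cross-check and standard
errors; the surfaces involved are small (≤ 7 free parameters) and the
full-restart fixture fits show no multimodality.

The test suite exercises two simulation benchmarks chosen to be decisive
yet quick: parameter recovery at the exposure-duration study's published
estimates with 10,000 witnesses per tree and 20 replicates (interior
parameters recovered with |bias| < 0.01; the boundary truth dA = 0 shows
the expected one-sided pile-up at zero), and the type-I error of the
ΔG²(1) test for a true guessing-equality restriction over 2,000
replicates of two conditions with 200 witnesses per tree at interior
generating values (empirical rejection rate within [0.03, 0.07] at
nominal 0.05). The generator emulates witnesses who behave exactly
according to the 2-HT process model with independent, identically
distributed decisions; it produces no participant-level heterogeneity,
no confidence ratings and no violations of the model's own assumptions,
so passing recovery tests demonstrates internal consistency of the
estimator, not validity of the model for any particular real data set.

## Numerical choices and limitations

- G² zero-cell convention: 0·ln(0/E) := 0; O > 0 with E = 0 → +∞ with a
  diagnostics note.
- EM tolerance 1e−10 on the log-likelihood; quasi-Newton `ftol` 1e−14,
  `gtol` 1e−10; logits clipped to ±30 at the start to avoid overflow.
- Default fitting seed 20220804; every stochastic entry point takes an
  explicit seed.
- Reports round parameters and G² to 2 decimals and p to 3, mirroring the
  source tables; JSON output keeps full precision.
- The engine is specialised to the two lineup trees; it is not a general
  MPT toolkit, and showup (single-suspect) designs, hierarchical
  participant-level extensions, Bayesian estimation and bootstrap
  intervals are out of scope.
- Fits here are desk-scale (≤ 16 categories, ≤ 7 free parameters, well
  under a second each); the eight-study reproduction completes in
  seconds.
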