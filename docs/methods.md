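# Methods

## The model

`blissassay` tests whether two agents (a fungicide, captan, and an
insecticide, thiamethoxam, in the motivating honey bee larval bioassay)
interact beyond independent action. Under Bliss independence, if the
control survives with rate s₀ and the single-agent groups with rates s₀·s_A
and s₀·s_B (s_A, s_B being the Abbott-corrected survival rates), the
combination survives with rate s₀·s_A·s_B.

The test embeds this in a binomial GLM for *survival* with a **log** link:

    log(p_surv) = β₀ + β_A·x_A + β_B·x_B + β_AB·x_A·x_B + γ_trial

with binary exposure indicators x_A, x_B. Coefficients are log
survival-probability ratios, so the Bliss product is exactly the additive
model: β_AB = 0 ⇔ independence. A likelihood-ratio test of β_AB on χ²(1)
decides; a significant negative β̂_AB is synergism (the combination kills
more than independence predicts), a significant positive one antagonism.
Trial fixed effects (reference-coded, first trial as baseline) absorb
batch-to-batch differences in natural mortality; any full-rank coding gives
the same LR.

Assumptions: per-subject binary outcomes independent given group and trial;
independent biological action *and* uncorrelated individual
susceptibilities to the two agents. The second assumption matters:
perfectly correlated susceptibilities make every survivor of agent A also
survive agent B, leaving combined survival at s₀·s_A > s₀·s_A·s_B — an
apparent antagonism with no pharmacological interaction. This failure mode
is demonstrable with the generator's frailty knob (below) but is not
estimable from a single 2×2 design, and the model does not correct for it.

## Constrained estimation

The log link only defines a probability where every linear predictor is
≤ 0, so the MLE is a linearly constrained concave maximization: SLSQP over
the constraints η ≤ 0 per distinct covariate pattern, started at the
least-squares projection of shrunken empirical log survival rates
(log((k+½)/(n+1)), always strictly feasible after an intercept shift), then
polished by damped interior Newton steps when no constraint is active.
SLSQP line searches can stall on an active constraint; a trust-region
constrained fallback then re-solves from the same start. Likelihood,
gradient and Hessian are computed on pattern aggregates (n_g, k_g), so fit
cost is independent of the number of subjects.

Numerical contracts:

- convergence: relative gradient < 1e-10 (interior) or optimizer success,
  max 500 iterations; failures raise, never pass silently;
- a fitted pattern probability within 1e-6 of 1 sets the `boundary` flag;
  LR statistics from boundary fits are still reported but the χ² reference
  is then approximate, and results carry the flag;
- a covariate pattern with zero survivors in a pattern-saturated design, or
  any diverging coefficient (|β| > 30), raises `DegenerateGroupError`: the
  log-link MLE is at −∞ and the test undefined. At the test level the same
  error is raised as soon as any of the four groups has zero survivors in
  scope. No continuity corrections are applied, by design;
- tiny negative LR values (> −1e-6) are clamped to 0 with a warning; larger
  ones raise.

The logit link is fitted by damped Newton–Raphson (step capped at 5 in the
max-norm) and exists for conventional mortality modelling and as a
cross-check; |η| > 15 at convergence is treated as complete separation.

## Test families and multiplicity

Interactions are tested at three dosage levels of agent B (each crossed
with the high dose of agent A, mirroring the assay design) on overall
survival and within each developmental stage — larva (days 1–6), prepupa
(days 7–9), pupa (days 10–14; deaths observed later but before emergence
attribute to pupa). Each test uses only its four groups (solvent control,
A alone, B alone at that dose, combination): the model has exactly the four
exposure cells, and dosage-specific tests are reported separately.

Holm's step-down procedure adjusts p-values within each declared family.
The default takes the nine stage-specific tests as one family and the three
overall tests as a second; with nine stage tests, a smallest raw p of
0.00486 (LR = 7.932) adjusts to 9 × 0.00486 = 0.0437 ≈ 0.044. Family
membership is user-configurable (`families=` in `run_interaction_family`),
because reasonable alternatives (all twelve jointly; per-scope families)
exist; the choice changes only the multiplicity penalty, not the
statistics.

The baseline for every test is the solvent-treated control, since all
treatments contain the solvent; the solvent-free control is carried in the
data model and summaries but excluded from GLM fits.

## Risk sets

Overall scope: one row per non-removed subject, outcome 1 iff it emerged.
Stage scope: subjects alive at stage entry, outcome 1 iff they did not die
in that stage (survival conditional on entry, so stage effects multiply to
the overall effect under the log link). Removed (e.g. contaminated)
subjects are censored: they contribute only to stages fully completed
before removal, and their count is reported. Stage attribution prefers the
recorded death stage; the day-range rule is the fallback, since day ranges
are typical rather than exact. Twice-daily checks are collapsed to integer
days — the models are binary per scope, so day resolution suffices.

## The synthetic generator

`simulate_assay` draws independent per-stage Bernoulli survival with
p = exp(β₀ₛ + β_Aₛ·x_A + β_Bₛ·x_B + β_ABₛ·x_A·x_B + γ_t): exactly the
structure the test assumes, so the Bliss null is exactly representable and
type-I error is interpretable. Death days are uniform within the stage's
day range (the models never use the day beyond stage attribution, so any
within-stage distribution is admissible; uniform is least informative).
One integer seed drives everything; per-trial sub-streams are spawned
deterministically, and identical (config, seed) gives byte-identical CSVs.

`default_design()` reproduces the 11-group, 3-trial assay layout: two
controls (n = 235, 236), captan at 100/500/2000 ng/ml (n = 92/96/96),
thiamethoxam at 10/70/1440 ng/ml (n = 94/95/94), and captan-2000 crossed
with each thiamethoxam dose (n = 109/109/103); 1,359 subjects in total,
split across trials as evenly as possible (the per-trial splits were not
published). Default coefficients, chosen once from the published summary
rates: across-trial control survival 0.74 (the intercept is calibrated
analytically for the trial-effect average, since the published rate pools
trials); captan effect from its reported ~90% relative mortality increase
at the high dose (the dose used in every combination; captan dose
differences were reported non-significant); a single thiamethoxam effect
from the medium dose's reported +120%, because the model carries one β_B
per stage; trial effects (0, −0.01, −0.02) per stage, a small batch
variation of the kind reported but not quantified; β_AB = 0 — the preset is
the global null. Effects are split evenly across stages on the log scale.

What the generator does *not* emulate: correlated susceptibilities (unless
the frailty knob — a per-subject Beta multiplier on the log-survival scale
— is switched on), dose–response within an agent beyond the three discrete
levels, time-varying hazards within a stage, and removal/contamination
events. Passing tests therefore show the estimator and test are correct
*under the model's own assumptions*; they cannot show robustness to
frailty-induced correlation, which the method's own caveat excludes.

## Simulation sizes

The calibration suites use: type-I error, 1,000 replicates of the
four-group design at 200 subjects/group/trial × 3 trials; family-wise
error, 300 replicates of the full 11-group design with all twelve tests
Holm-adjusted as one family; recovery, 400–500 replicates per interaction
value at ~1,000 subjects/group. Monte-Carlo standard errors
(√(r(1−r)/reps) ≈ 0.007 at r = 0.05, reps = 1000) are reported alongside
every rate, and bands in tests are ±3 MC SE. Replicates with a degenerate
group are excluded from rate denominators and counted explicitly.

## Known limitations

- Boundary MLEs (fitted survival of 1) are flagged, not corrected; the LR
  null distribution there is a χ² mixture, and p-values are conservative
  approximations.
- The constrained fit contract is a defined superset of what off-the-shelf
  log-binomial fitters do near the boundary; coefficient estimates agree in
  the interior, behaviour at the boundary is this package's own, documented
  choice.
- Zero-survivor groups abort the affected test rather than being patched
  with continuity corrections; at the family level the failure is recorded
  and the remaining members are still adjusted.
- Per-stage mortality summaries are conditional on stage entry; fractions
  of the initial cohort are derivable from the risk tables if preferred.
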