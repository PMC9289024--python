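# Methods

`sepsis-safety` audits treatment policies for septic ICU patients against
expert-defined hazard scenarios, retrains a tabular RL policy under a
safety-reshaped reward, and evaluates policies off-policy. This note records
the models, the tunable parameters and their defaults, what the synthetic
cohort does and does not emulate, and the numerical choices that matter.

## The decision problem

Sepsis resuscitation is modelled as a discrete-time decision process on a
4-hour grid. At each step a clinician (or policy) chooses an intravenous
fluid volume and a vasopressor rate; the stay ends in survival or death. The
package treats the problem as a finite MDP:

* **States.** k-means clusters (default `k = 20` at desk scale; hundreds at
  full scale) of standardized observables — MAP, CVP, cumulative fluid
  balance, urine output, SOFA, lactate, sedation, total fluid input, weight —
  plus two absorbing terminals (survival, death). Standardization statistics
  come from the fitting cohort only; assignment is nearest-centroid with
  exact ties broken toward the lower centroid id.
* **Actions.** A 5×5 dose grid per drug: bin 0 is an exactly-zero dose; bins
  1–4 split the observed non-zero doses at their 0.25/0.5/0.75 quantiles
  (left-closed bins, last bin right-closed). The composed index is
  `a = 5·fluid_bin + vaso_bin ∈ {0,…,24}`. Each bin is represented by its
  within-bin median observed dose (exactly 0 for bin 0), so "no fluids" and
  "no vasopressors" hazard conditions are exactly decidable for policy
  recommendations. Drugs with fewer than four distinct non-zero doses fall
  back to fewer bins with a warning; the 25-wide index space is preserved.
* **Transitions.** Empirical frequencies `P(s'|s,a) = n(s,a,s')/n(s,a)`.
  Pairs observed fewer than `min_count = 5` times are inadmissible and are
  never recommended — a safety-relevant choice, since it forbids dose
  combinations never seen in the data. A visited state whose actions are all
  below `min_count` raises an error by default; the pipeline instead admits
  the state's most-observed action (`on_no_admissible="relax"`), recorded in
  the run manifest.

## Hazard scenarios

Four scenarios capture under- and over-dosing of the two drugs (thresholds
are config keys; comparators are applied literally, boundary-inclusive
exactly as written):

| id | at risk (patient state) | unsafe action |
|----|--------------------------|---------------|
| A | MAP < 55 mm Hg | no vasopressor AND fluids ≤ 20 mL/h |
| B | MAP > 95 mm Hg | vasopressor > 0.65 µg/kg/min |
| C | MAP ≤ 55 AND CVP ≤ 5 mm Hg | fluid rate exactly 0 |
| D | MAP ≥ 75, balance > 10 L, CVP ≥ 15 | fluids > 240 mL/h |

A decision is unsafe only at an at-risk step. Policy recommendations are
resolved through the bin-representative doses and evaluated at the same
at-risk steps as the recorded behaviour, so the at-risk denominator N is
identical for every agent — the form the z test below requires. A step
unsafe under several scenarios counts once in the any-scenario union and
once per scenario in per-scenario reports. C is a subset of A's at-risk
region: withholding both drugs from a low-CVP hypotensive patient is unsafe
under both definitions.

MAP-threshold sweeps re-run the flagging over a grid (defaults: 45–60 mm Hg
for A/C, 85–105 for B, 70–85 for D, in 2.5 steps) to show that conclusions
do not hinge on one cut-off.

## Human-vs-policy statistics

For one scenario, both agents are observed on the same N at-risk steps with
unsafe counts x̂_Human and x̂_AI. Modelling unsafe decisions as Bernoulli, the
null p_Human = p_AI is tested with

    z = (p̂_AI − p̂_Human) / √( p̂ (1 − p̂) · 2/N ),   p̂ = (p̂_Human + p̂_AI)/2,

with p values from the standard Gaussian CDF; the default alternative is
one-sided (policy less unsafe than human), two-sided available by flag. When
the pooled p̂ is 0 or 1 both counts coincide and z is defined as 0. No
multiplicity adjustment is applied across threshold sweeps by default
(a Bonferroni helper exists). Calibration and power of this test are
exercised directly in the suite (null rejection ≈ 5%, power > 0.9 for
0.5 vs 0.4 at N = 1000).

## Feature attribution of unsafe clinician decisions

Per scenario, a gradient-boosted tree classifier (xgboost; 150 trees, depth
3, learning rate 0.1, seeded, single-threaded) predicts whether the
clinician's decision at an at-risk step was unsafe from the step's feature
vector. Per-observation signed attributions come from exact TreeSHAP
(`pred_contribs`, log-odds scale); features are ranked by mean absolute
attribution and reported relative to the top feature, with a direction
summary (sign of the feature-vs-attribution correlation).

## Reward reshaping and policy learning

The base reward is terminal only: +R on survival, −R on death
(`R = 100`, `γ = 0.99`; both config keys). Safety reshaping subtracts an
intermediate penalty at every state-action:

    r(s,a) = −P · f(s,a),

where `f(s,a)` is the fraction of observed instances of (s,a) flagged unsafe
under the any-scenario union and `P = 30` points by default. The expected
per-instance form preserves the mean of the instance-level penalty across a
heterogeneous cluster; a binary majority-flagged mode is available. `P = 0`
reproduces the original reward exactly (bit-identical policies under fixed
seeds, asserted in the suite).

Policies are learnt two independent ways:

* **Q-learning** (production path): repeated sweeps over the empirical
  transition list in seeded shuffled order, per-pair learning rate
  `α = α₀/(1 + decay·visits)` (α₀ = 0.6, decay = 0.05), stopping when the
  sup-norm Q change between consecutive sweep-end snapshots falls below
  `tol = 1e-4` (error on non-convergence). Because each sweep replays the
  full dataset (sampling without replacement), the per-sweep drift decays
  with α and the rule terminates.
* **Exact value iteration** on the estimated model to sup-norm 1e-10, used
  purely as a verification oracle. Greedy policies from the two routes agree
  on batteries of random MDPs; true value near-ties at the size of the
  Q-learning tolerance (~1e-4 top-2 gap) are the one case where they can
  differ.

Greedy ties break toward the lowest action index, i.e. the lowest composed
doses.

## Off-policy evaluation

The behaviour policy is estimated as per-state empirical action frequencies
with additive smoothing λ = 0.01 over admissible actions; greedy policies
are softened to `1 − ε` on the greedy action (ε = 0.01) with the remainder
uniform over other admissible actions, keeping importance ratios finite.
Per-stay weights are products of per-step probability ratios; the value
estimate is weighted importance sampling (WIS), the self-normalized form,
chosen over plain importance sampling for variance control at the cost of an
O(1/ESS) bias. Confidence bounds are a seeded stay-level bootstrap
(B = 2000 by default; stays are the independent units), reported as median
and IQR. Returns are computed under the unpenalized reward by default so the
three agents are compared on one scale; the penalized scale is available by
flag and mechanically lowers any policy's value. The estimator is verified
against exact policy evaluation on a fully known MDP using a behaviour
policy with strong overlap (0.85 target / 0.15 empirical mixture, effective
sample size ≈ 0.6 n); with weak overlap the WIS bias, not the estimator's
correctness, dominates the comparison.

## The synthetic cohort

The generator emulates the statistical structure such an audit runs on,
with known ground truth. Per stay: a latent severity (clipped normal, small
per-step drift) drives MAP decline, urine suppression, lactate rise, SOFA,
and a per-step logistic death hazard
`σ(−6.4 + 2.1·severity + 0.18·hypotensive-steps + 0.07·(balance − 5 L)₊)`.
MAP follows a mean-reverting walk around a per-stay set point (87 ± 10 mm Hg)
with additive drug effects: `5·log1p(fluid/250)` and `22·vaso`, both scaled
by preload dependence — fluid responsiveness is high on the steep (low-CVP)
part of the Starling curve and flat when overloaded; vasopressors lose
effect in frank hypovolaemia. CVP is a noisy affine function of cumulative
balance (5 + 1.1/L); balance is the exact running sum of inputs minus urine.

The behaviour policy targets MAP 65–90 with realistic heterogeneity:
lognormal bolus-size spread, fluid+pressor combination therapy, and a
pressor-only strategy reserved for volume-replete patients (CVP ≥ 8).
Whenever a scenario's at-risk condition holds, the policy takes that
scenario's unsafe action with a configured propensity (defaults
A 0.5, B 0.03, C 0.5, D 0.35, near the observed clinician rates). Scenario
A's override is exactly no treatment, so realized counts — tallied by the
hazard predicates on the final action and therefore reproducible by
re-flagging the emitted file — recover the configured propensity exactly in
distribution for A, B and D; C's realized rate additionally includes
A-type withholding at overlap steps.

All randomness is drawn up front from one seeded generator: identical
configs give byte-identical files, and raising a mortality coefficient can
only move deaths earlier (monotone harm, exact per seed). Emitted features
are rounded to fixed decimals (doses and volumes to whole mL) so CSV files
round-trip exactly. Severity is deliberately not emitted: clustering faces
the same partial observability as on real data.

**What it does not emulate** (hence what passing tests do not show about
real data): pharmacokinetics, comorbidities, missing or irregularly sampled
measurements, informative censoring, end-of-life care decisions, and
post-discharge time — the 90-day outcome collapses to survival of the
simulated 72-hour episode. Policy values and unsafe-decision rates computed
here characterize the pipeline's behaviour under a known model, not any
clinical population.

## Problem sizes and determinism

The suite and the acceptance script run the full pipeline at 2000 stays ×
≤18 steps with k = 20 states, B = 2000 bootstrap resamples, 50 random MDPs
for the solver cross-check, and 10,000/2,000 replicates for test
calibration — sizes chosen so a complete desk run finishes in well under a
minute while every statistical check retains adequate power. Every
stochastic stage takes an explicit seed; run manifests record parameters,
seeds, and artifact hashes, and a repeated run under the same config
reproduces identical outputs.

## Known limitations

* With coarse state spaces (small k), clusters mix at-risk and benign steps;
  the instance-level penalty then only imperfectly encodes "this
  recommendation would be unsafe here", and safety orderings between
  learnt policies at rare scenarios (C above) are statistical rather than
  guaranteed — mirroring the non-significant fourth scenario in this class
  of audits.
* The z test assumes a shared at-risk denominator and independence across
  steps; within-stay correlation is ignored, as in the method it implements.
* WIS confidence bounds understate uncertainty when importance weights are
  heavy-tailed (low effective sample size); the reported bootstrap IQR
  should be read together with the smoothing and softening parameters.
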