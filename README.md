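# sepsis-safety

Safety assurance for reinforcement-learning sepsis treatment policies.

Offline RL can learn intravenous-fluid and vasopressor dosing strategies for
septic ICU patients from recorded care, but a policy that improves expected
survival can still recommend decisions clinicians would call obviously
dangerous. This package implements, as a tested and reusable pipeline, the
safety-assurance analysis for such a policy:

1. **Hazard auditing** — four expert-defined hazard scenarios (withholding
   treatment in hypotension; maximum pressors despite hypertension; no fluids
   in hypovolaemic hypotension; maximum fluids in fluid overload) are applied
   to recorded clinician behaviour and to policy recommendations on the same
   at-risk steps, across a range of blood-pressure thresholds.
2. **Human-vs-policy statistics** — unsafe decisions among the N at-risk
   steps are compared with the pooled two-proportion z test
   `z = (p̂_AI − p̂_Human)/√(p̂(1−p̂)·2/N)`, `p̂ = (p̂_Human+p̂_AI)/2`.
3. **Feature attribution** — gradient-boosted trees predict unsafe clinician
   decisions per scenario; exact TreeSHAP values say which patient features
   drive them.
4. **Safety-constrained retraining** — the reward (±100 on survival/death,
   γ = 0.99) is reshaped with an intermediate penalty −P·f(s,a), where f is
   the flagged fraction of observed instances of that state-action
   (P = 30 points by default), and the policy is relearnt by Q-learning over
   the empirical transition list, with an exact Bellman solver as independent
   oracle.
5. **Off-policy evaluation** — behaviour, original, and safety-constrained
   policies are valued by weighted importance sampling with stay-level
   bootstrap confidence bounds (B = 2000, median and IQR).

Real ICU trajectory tables (one row per 4-hour step: MAP, CVP, cumulative
balance, urine output, SOFA, lactate, sedation, fluid input, weight, doses,
90-day outcome) can be supplied as CSV. The package also ships a synthetic
ICU cohort generator with known ground truth — planted per-scenario unsafe
propensities, severity-linked mortality, preload-dependent drug effects — so
the entire analysis is testable without access to restricted clinical data.
See `docs/methods.md` for the models and their assumptions.

## Worked example

Run the full pipeline on a synthetic cohort of 500 stays:

```bash
sepsis-safety all -o demo -v --n-stays 500 --seed 42 --k 12
```

which logs, stage by stage:

```
simulate: 500 stays, 8444 steps, mortality 0.130
prepare: k=12 states, 25/25 fluid/vaso bins in use
flag: per-scenario (N, x_human) = {'A': (158, 74), 'B': (735, 23), 'C': (6, 6), 'D': (51, 24)}; union 121
original: Q-learning converged in 1775 sweeps (penalty=0)
safe: Q-learning converged in 2313 sweeps (penalty=30)
ope: {'behaviour': 61.38, 'original': 77.76, 'safe': 77.76}
```

`flag` reports, per scenario, the number of at-risk steps N and how many of
the clinician's decisions at those steps were unsafe — e.g. at 158
hypotensive steps the (synthetic) clinicians withheld treatment 74 times,
close to the planted 50% propensity. `demo/report.md` then compares the
three agents on the shared denominators:

```
scenario    agent   N  x  proportion
       A    human 158 74    0.468354
       A original 158  4    0.025316
       A     safe 158  4    0.025316
       B    human 735 23    0.031293
       B original 735  0    0.000000
       ...

## Off-policy policy value (unpenalized reward; median [IQR])
- behaviour: 61.37 [59.67, 63.12]
- original: 77.71 [74.01, 80.69]
- safe: 77.71 [74.01, 80.69]
```

Both learnt policies avoid almost all flagged decisions (4/158 vs the
clinicians' 74/158 in scenario A) while their estimated value exceeds the
behaviour policy's; the safety penalty did not cost value here. The run
directory also contains the threshold-sweep significance curves
(`sweep_*.csv`, `fig_threshold_sweeps.png`), per-scenario TreeSHAP rankings
(`attribution_*.csv`), the 25-action recommendation histograms, and a JSON
manifest per stage (parameters, seeds, artifact hashes) for reproducibility.

The same analysis is available as a library (`sepsis_safety.generate_cohort`,
`flag_cohort`, `two_proportion_ztest`, `q_learning`, `bootstrap_value`, …);
every CLI stage is a thin wrapper over those functions.

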