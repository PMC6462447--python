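# seqrisk

Analysis pipeline for **sequence-dependent risky choice** in binary
gamble-versus-safe tasks, of the kind used to measure probability distortion
in rhesus macaques: animals repeatedly choose between a risky juice reward
(0.5 ml with probability *p*, otherwise nothing) and a safe magnitude, with
the gambles either pseudorandomly **MIXED** within a session or presented one
per block (**REPEATED**). The package is aimed at behavioral neuroscientists
and neuroeconomists who need to go from trial tables to fitted
prospect-theory parameters — and at anyone who wants to study how the
*ordering* of gambles reshapes the measured probability weighting.

It provides, as plain Python and a thin CLI:

- **Psychometric certainty equivalents (CE).** Per gamble, the fraction of
  safe choices versus safe magnitude *m* is fit by maximum likelihood with a
  logistic `P(safe|m) = 1/(1+exp(-(m - x0)/sigma))`; the inflection `x0` is
  the CE. CE > EV flags risk seeking, CE < EV risk aversion.
- **Prospect-theory discrete-choice fitting.** Choices follow a softmax
  `P(G) = 1/(1+exp(-lambda (V_G - V_S)))` over subjective values
  `V = u(m_high) w(p_high) + u(m_low)(1 - w(p_high))`, with power utility
  `u(m) = (m/0.5)^rho` and one of four weighting families: one- and
  two-parameter Prelec (`w(p) = exp(-beta(-ln p)^alpha)`), Tversky–Kahneman
  (`p^eps / (p^eps + (1-p)^eps)^(1/eps)`) and Gonzalez–Wu log-odds
  (`delta p^gamma / (delta p^gamma + (1-p)^gamma)`). Parameters are estimated
  by Nelder–Mead MLE (log-scale, multi-start) and families compared by BIC;
  a Monte-Carlo simulate-and-refit harness validates the estimation.
- **Marschak–Machina triangle geometry.** Theoretical and psychometrically
  elicited indifference lines over three fixed magnitudes (0, 0.25, 0.5 ml);
  a regression of line angle on line index classifies fanning-out (inverse-S
  weighting, `alpha < 1`) versus fanning-in (S-shaped, `alpha > 1`),
  independently of utility curvature.
- **Trial-history analyses.** Standardized logistic choice regressions with
  lagged gamble EVs, a win-stay/lose-shift model, outcome-conditional
  prospect-theory fits, and a two-parameter value-updating agent
  (`V_G = EV ± eta` after a previous gamble win/loss) whose interaction with
  MIXED vs REPEATED orderings displaces CE curves in opposite directions.
- **Synthetic data.** Everything runs on simulated sessions that reproduce
  the task design (9 gamble probabilities × 11 safe magnitudes × n repeats,
  side-balanced, MIXED or REPEATED), so the full pipeline is testable with
  no recorded data.

## Worked example

Simulate one MIXED session from a known risk-seeking, inverse-S agent and
refit it:

```python
from seqrisk import CPTParams
from seqrisk import synthetic, cpt, psychometrics

plan = synthetic.default_plan("MIXED", reps_per_pair=6, seed=7)   # 594 trials
agent = CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67)
records = synthetic.simulate_session(plan, agent, seed=7, session_id="demo")

fit = cpt.fit_mle(records, family="prelec1", seed=0)
print(fit.params.lam, fit.params.rho, fit.params.alpha, fit.bic)
# 10.77  1.89  0.717  301.7

ces = psychometrics.estimate_all_ces(records)
print(ces[["gamble_p", "ce_ml", "ev_ml", "attitude"]].head(3).round(3))
#    gamble_p  ce_ml  ev_ml attitude
# 0       0.1  0.172   0.05  seeking
# 1       0.2  0.225   0.10  seeking
# 2       0.3  0.241   0.15  seeking
```

The generating parameters (softmax temperature 10, convex utility rho = 2,
inverse-S weighting alpha = 0.67) are recovered from a single session
(10.77, 1.89, 0.717), and the estimated CEs sit above the EVs for all but the
highest probability, the behavioral signature of overweighted low
probabilities combined with convex utility. `cpt.predicted_ce(fit.params, 0.2)`
returns 0.238 ml, matching the measured CE at p = 0.2 (0.225 ml) to within
the psychometric estimation error.

The same stages are available from a shell (see `examples/reversal.yaml` for
the config format):

```bash
seqrisk simulate --config examples/reversal.yaml
seqrisk fit seqrisk-out/trials.tsv --config examples/reversal.yaml
seqrisk reversal --config examples/reversal.yaml   # MIXED vs REPEATED run
seqrisk triangle --alpha 0.67 --rho 2 --out seqrisk-out
```

Trial tables are tab-separated text (`session_id, trial_index, condition,
gamble_p, gamble_m, safe_m, gamble_side, chosen, outcome_ml, rt_ms`) and
round-trip losslessly through `seqrisk.pipeline.read_trials`/`write_trials`.

## Layout

| module | contents |
| --- | --- |
| `seqrisk.types` | `Gamble`, `TrialRecord`, `SequencePlan`, parameter containers |
| `seqrisk.synthetic` | task designs, sequence builders, simulated agents |
| `seqrisk.psychometrics` | choice ratios, logistic CE fits, risk-attitude tables |
| `seqrisk.cpt` | utility/weighting primitives, MLE, BIC comparison, recovery |
| `seqrisk.triangle` | indifference lines, fanning regression, shift correlation |
| `seqrisk.history` | lagged regressions, WSLS, conditional fits, RL model |
| `seqrisk.pipeline` / `seqrisk.cli` | trial-table I/O, run configs, subcommands |

See `docs/methods.md` for the modelling assumptions, parameter conventions,
numerical choices and known limitations.
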