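# Methods

This note documents the models implemented in `seqrisk`, the conventions and
defaults behind them, the numerical choices that matter, and what the
synthetic-data generator does and does not emulate.

## Task model and units

All rewards are juice volumes in ml on [0, 0.5]; `m_max = 0.5` ml anchors the
utility scale. A *gamble* is a discrete lottery; the standard task gamble
pays 0.5 ml with probability `p ∈ {0.1, …, 0.9}` and nothing otherwise, and a
*safe* option is a degenerate lottery. One session presents every
gamble × safe pair (11 safe magnitudes, 0–0.5 ml in 0.05 ml steps) a fixed
even number of times (default 6, i.e. 594 trials), with left/right positions
exactly balanced per pair. In **MIXED** sessions all pairs are shuffled
uniformly; in **REPEATED** sessions each gamble occupies one contiguous
block (block order is a seeded shuffle — the ordering of blocks is not
otherwise constrained) with safes shuffled within the block. The MIXED
shuffle is unconstrained (immediate gamble repeats are allowed). The
probability-1 "gamble" is excluded from certainty-equivalent designs:
a certain option has no risk attitude to measure.

Error trials (no choice made) are not generated by default; an optional
`error_rate` inserts them so that downstream exclusion filters can be
exercised. Randomness uses one root seed with per-session child streams
(numpy `SeedSequence.spawn`), so any session is independently reproducible.

## Certainty equivalents

For each gamble, the per-safe-level fraction of safe choices (error trials
excluded) is fit with the two-parameter logistic

    P(safe | m) = 1 / (1 + exp(-(m - x0) / sigma)),

by **Bernoulli maximum likelihood on the trial counts**, not least squares on
the ratios: the ratios derive from binary trials, so levels with more repeats
carry proportionally more weight. The inflection `x0` is the certainty
equivalent; `sigma > 0` is the curve's temperature. A fit is attempted only
when at least 3 distinct safe levels have at least 4 repeats each (the
eligibility filter); all-safe or all-gamble data are non-identifiable and
returned flagged, with `x0` placed one level step outside the tested range on
the appropriate side. Fitted inflections outside [0, 0.5] ml are retained but
flagged `extrapolated`: the curve's crossing is meaningful but unreliable
there. CEs within 1e-3 ml of the EV are classified risk *neutral* — below
the resolution at which rewards are delivered — otherwise CE > EV is
*seeking* and CE < EV *averse*.

## Discrete-choice model

Choice probabilities follow a softmax on subjective values,
`P(G) = expit(lambda (V_G - V_S))`, with the rank-dependent value of a
(≤ 2-outcome) lottery

    V = u(m_high) · w(p_high) + u(m_low) · (1 - w(p_high)),
    u(m) = (m / 0.5)^rho.

`rho > 1` is convex utility (risk seeking), `rho < 1` concave, `rho = 1`
linear. Four weighting families are implemented (parameter counts in
brackets): Prelec-1 `exp(-(-ln p)^alpha)` [3 free parameters total],
Prelec-2 `exp(-beta (-ln p)^alpha)` [4], Tversky
`p^eps / (p^eps + (1-p)^eps)^(1/eps)` [3], Gonzalez–Wu
`delta p^gamma / (delta p^gamma + (1-p)^gamma)` [4]. Endpoints w(0) = 0 and
w(1) = 1 are fixed by continuity. For Prelec-1, `alpha < 1` is the inverse-S
(overweights low, underweights high probabilities), `alpha > 1` the S-shape,
with the fixed point at p = 1/e.

The attention variant applies weights `(1-k)` and `k` to the gamble and safe
values inside the softmax; `k = 0.5` recovers the standard model up to a
rescaling of lambda, and `k > 0.5` means the safe option is overweighted.
Gambles with more than two distinct outcomes (triangle-interior lotteries)
are out of scope for valuation.

### Estimation

The negative log likelihood `-Σ [y ln P_G + y' ln P_S]` is minimized by
Nelder–Mead with positive parameters on the log scale (k on the logit
scale), 10 seeded restarts by default jittered (sd 0.7 in log space) around
(lambda = 5, rho = 1, shape = 1, k = 0.5); tolerances `fatol = 1e-8`,
`xatol = 1e-6`; log-parameters clamped to ±30 so simplex excursions cannot
underflow. Choice probabilities are clipped to [1e-12, 1 - 1e-12]. Because
the model is history-free, the likelihood depends on the data only through
per-(gamble, safe) choice counts; fitting aggregates trials into those cells,
which makes a 594-trial fit take tens of milliseconds without changing the
likelihood. BIC is `k ln n + 2(-LL)` with n the trial count. Fits are done
per session pooled over gambles by default; passing any subset of records
fits that subset (e.g. one elicitation sequence, or sessions pooled).

For the (0.5 ml @ p) gamble family the model-predicted CE has the closed
form `CE = 0.5 · w(p)^(1/rho)`, tested against numeric inversion of u.

### Monte-Carlo validation

`parameter_recovery` simulates datasets on the standard design and refits
them. Since trials are iid given the design, per-cell gamble-choice counts
are drawn directly as Binomial(reps, P_G) — exactly equivalent to
trial-by-trial simulation and much faster. The validation grids are
rho ∈ {0.20, 0.50, 1.00, 1.50, 3.00} at alpha = 0.67, and
alpha ∈ {0.33, 0.67, 1.00, 1.50, 3.00} at rho = 2, both with lambda = 10 and
the 9 × 11 × 6 design. The acceptance suite uses 200 replicates per cell
(about two minutes per grid on one core; percentile 95% CIs stabilize well
below that), asserting that each generating value lies inside its percentile
95% CI with median bias under 10%. The recovery harness uses 3 optimizer
restarts per fit — with aggregated likelihoods and this design the
multi-start already reaches the global optimum in all spot checks, and 10
restarts changes estimates only in the fourth decimal.

## Marschak–Machina triangle

The triangle spans lotteries over m1 < m2 < m3 (defaults 0, 0.25, 0.5 ml)
with p1 (worst outcome) on x and p3 (best) on y. Fixed gambles sit on the
axes — x-axis gambles are (m1, m2) lotteries, y-axis gambles (m2, m3), both
valued with the rank-dependent form above — and each is connected to the
hypotenuse point of equal subjective value:

    p3* = w⁻¹(V(fixed) / u(m3)),   w⁻¹(q) = exp(-(-ln q)^(1/alpha)).

A fixed gamble at least as valuable as the certain best outcome has no
interior solution and is rejected. Lines are indexed 1–8 from the
lower-right corner to the top-left: x-axis fixed gambles from p1 = 0.8 down
to 0.2, then y-axis from p3 = 0.2 up to 0.8. Slope is reported as the angle
against the horizontal axis in degrees. Psychometric elicitation presents a
fixed gamble against hypotenuse probes (default p3 ∈ {0.1, …, 0.9}; the probe
grid is a package default, chosen to mirror the gamble-probability grid) and
takes the logistic inflection of P(choose hypotenuse) as p3*; inflections
fitted marginally outside [0, 1] are clipped back onto the hypotenuse.

OLS of angle on index classifies the fanning direction: positive
coefficients mean fanning-out (inverse-S weighting), negative fanning-in
(S-shaped), with linear weighting giving parallel lines whatever the utility
curvature — utility shifts the mean angle but never the sign of the
regression. One caveat the closed form makes explicit: angles are *not*
strictly monotone in the 1–8 index (the top-left line can fall a fraction of
a degree below its neighbour), so monotonicity is only asserted along each
axis; the regression sign is unaffected. The condition comparison computes,
per line, the REPEATED − MIXED shift in p3* for modeled and measured lines
and reports their Pearson correlation over complete pairs.

## Trial history and the value-updating agent

Logistic choice regressions are fit per session with statsmodels and
standardized by `beta · SD(x) / SD(y)`, with SD(y) the sample SD of the
binary choice variable; coefficients are then tested across sessions with
one-sample t-tests at 0.05 (no multiple-testing correction within this
module). The lagged-EV regression uses the *offered* gamble EV up to 8
trials back; lags count trials (including error trials), and the first 8
trials of each session are dropped. `Outcome_past` (1 = previous gamble won)
is defined only on trials whose previous trial's gamble was chosen, and the
win-stay/lose-shift model is fit on exactly those trials. The WSLS-vs-basic
BIC comparison excludes under-sampled sessions; the exclusion threshold is
applied to the session's full-design per-pair counts (at least 4 repeats of
every pair), since applying it to the post-filter subset would empty any
well-formed design of moderate length.

The value-updating (reinforcement-learning) agent codes values linearly in
ml — `V_S` is the safe magnitude, and

    V_G(t) = EV + eta · (preWin(t) - preLoss(t)),

a **one-trial memory**: the indicators refer to the immediately preceding
trial's gamble outcome regardless of gamble identity, and the value is not
updated when the safe option was chosen. A cumulative variant
(`cumulative=True`), in which the ±eta increments accumulate over the
session, is provided as an alternative reading of "updated, starting from
its EV"; it is not the default because the accumulated offset is shared
across gambles and drives both orderings toward S-shaped patterns rather
than separating them. Because the previous-outcome indicator is data, the
(lambda, eta) likelihood is an ordinary logistic; per-session MLE uses
Nelder–Mead (eta unconstrained in sign, lambda log-scale, initialized at
20 /ml), and fits whose lambda collapses below 0.5 /ml are flagged — with a
flat softmax, eta has no leverage on the likelihood (typical fitted lambdas
are ~20 /ml, and the per-session eta estimator has an SE of roughly 0.01 ml
on a 594-trial session).

### The sequence-reversal simulation

`run_reversal_experiment` and `simulate_rl_ces` simulate the value-updating
agent (default eta = 0.0045 ml, the scale recovered from behavior in this
paradigm) in both orderings, 50 sessions per condition, then estimate CE
curves psychometrically and fit the pooled Prelec-1 model per condition.
The simulation lambda is 20 /ml, derived once from the estimation
validation: that validation fixes lambda = 10 on utilities normalized by
0.5 ml, and with linear coding the identical choice stochasticity on the ml
scale is 10 / 0.5 = 20 /ml.

What the one-trial rule implies deserves spelling out. In REPEATED blocks
the previous gamble is the current gamble, so the mean value shift is
`eta · (2p - 1) · P(gamble chosen)` — negative for low p, positive for high
p — which tilts the fitted distortion toward the S-shape
(pooled alpha ≈ 1.01–1.03 at these settings). In MIXED sequences the
previous trial is independent of the current gamble, so the shift is a
p-independent constant (≈ +eta · E[previous-outcome sign] ≈ +0.0005 ml);
a constant CE elevation is absorbed almost entirely by the utility exponent,
leaving the MIXED distortion at alpha ≈ 1.00 rather than below it. The
model therefore reproduces the *relative* separation of the two CE curves
(REPEATED below MIXED at low p, above at high p — the curves cross, with
displacements of a few thousandths of a ml, bounded above by eta) and the
S-shaped side of the reversal, but a full absolute inverse-S in MIXED is not
a consequence of the one-trial update at this step size. The CE-curve
crossing is assessed by regressing the per-probability REPEATED − MIXED CE
difference on p (a positive slope = crossing), which uses all nine
probability levels rather than two noisy endpoints.

## Synthetic data: what it does and does not emulate

The generator reproduces the design structure (pair grids, repetition
counts, side balance, MIXED/REPEATED orderings, probabilistic outcome
delivery) and the agent families above. It does not emulate: motivational
drift or satiety within sessions, side biases, lapses other than the
optional uniform error rate, reaction times (stored but never generated),
magnitude-dependent motor costs, or learning of the cue–reward mapping
(agents know the offered lotteries exactly). Passing tests therefore show
that the estimators recover what the models generate under the task design —
not that real animals satisfy those models.

## Degenerate inputs and edge conventions

- `w(0) = 0`, `w(1) = 1` by continuity in every family.
- Safe options valued as u(m); p = 1 "gambles" collapse to safe options.
- Empty record sets, single-trial variability requests, sub-eligibility CE
  data, < 3 indifference lines, and < 3 complete line pairs are rejected
  with explicit messages rather than returning NaNs.
- Non-identifiable psychometric fits (one-sided ratios) and attention or RL
  fits with collapsed temperature are returned flagged, not dropped.
- Ties in BIC comparisons rank by the table's stable sort; the `best` flag
  marks the minimum.

## Known limitations

- Valuation covers at most two distinct outcomes; triangle-interior
  (three-outcome) lotteries can be generated and plotted as points but not
  valued — full indifference *curves* are out of scope.
- All outcomes are gains; there is no reference point or loss aversion.
- The Tversky family is non-monotone for very small eps (< ~0.28); the
  optimizer may legitimately visit that region, but fitted values on
  realistic data stay well above it.
- Bootstrap CIs for the outcome-conditional fits resample trials, not
  sessions, and so ignore session-level heterogeneity.
- The value-updating model's one-trial memory caps any CE displacement at
  ±eta; longer-memory learning rules are deliberately not implemented.
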