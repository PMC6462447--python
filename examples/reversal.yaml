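# Run configuration for the MIXED-vs-REPEATED reversal experiment.
#
# The value-updating agent codes values linearly in ml: the gamble value
# starts from its objective EV and gains/loses `eta` ml after a previous
# gamble win/loss; `lam` is the softmax temperature per ml.
seed: 0
n_sessions: 50
reps_per_pair: 6
condition: MIXED          # used by the `simulate` subcommand only
agent:
  kind: rl                # "rl" (lam, eta) or "cpt" (family, lam, rho, ...)
  lam: 20.0
  eta: 0.0045
stages: [reversal]
output_dir: seqrisk-out
error_rate: 0.0
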