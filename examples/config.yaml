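# Example configuration for the ledgerfed CLI.
#
#   ledgerfed generate  --config examples/config.yaml --out runs/cohort
#   ledgerfed simulate  --config examples/config.yaml --out runs/sim
#   ledgerfed ablate    --config examples/config.yaml --out runs/ablation
#
cohort:
  n_patients: [150, 150, 60]   # one entry per site; a single entry means one site
  prevalence: 0.12             # base in-hospital mortality prevalence
  signal: 1.0                  # scales every severity slope (0 = no-signal control)
  label_slope: 3.0             # logistic link between latent severity and outcome
  horizon_hours: 48
  seed: 3

consortium:
  trainer_ids: [hospital_a, hospital_b]
  validator_id: coordinator
  rounds: 5
  local_epochs: 1
  aggregation: reputation_weighted   # or: uniform
  seed: 3

governance:
  lam: 1.0          # incentive strength
  mu: 0.5           # audit-fail penalty
  ema_beta: 0.9
  reputation_decay: 0.05
  reputation_gain: 1.0
  reputation_floor: 0.05
  reward_cap: 1.0

training:
  lr: 5.0e-4
  weight_decay: 1.0e-4
  batch_size: 32
  max_epochs: 120
  patience: 15
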