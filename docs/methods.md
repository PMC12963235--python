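# Methods

`ledgerfed` is a desk-scale, single-process simulator of a blockchain-governed
federated learning consortium for ICU in-hospital mortality prediction. It
couples five layers: a synthetic multi-center EHR generator, a preprocessing
pipeline with strict train-only statistics, a NumPy transformer risk model, a
hash-chained ledger with simulation-grade signatures, and the governance stack
(stake-proportional validator sampling, reputation-weighted aggregation, token
incentives, smart-contract agreements). This note records the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic experiments do and do not establish.

## Synthetic cohort model

Real credentialed ICU extracts cannot ship with a package, so every stage is
exercised on cohorts drawn from a known generative process:

* **Latent severity.** Each patient carries `z ~ N(0, 1)`. The binary
  in-hospital mortality label is drawn from `P(Y=1|z) = sigmoid(a + b z)` with
  slope `b = 3.0` by default; the intercept `a` is calibrated per site so that
  `E_z[sigmoid(a + b z)]` equals the site's target prevalence (Gauss–Hermite
  quadrature for the expectation, bracketing root-find for `a`). Optional
  label noise flips the drawn label with a per-site probability. With
  `b = 3.0` the Bayes-optimal AUROC of `z` against the labels is ≈ 0.92,
  leaving clear headroom between a learnable model and chance.
* **Trajectories.** Each of the default 16 variables (vitals and labs with
  order-of-magnitude realistic means/sds) follows a stationary AR(1) path on a
  30-minute tick grid, mean `baseline_mean + severity_slope · z`, stationary
  sd `baseline_sd`, per-tick autocorrelation per variable. Severity slopes
  are expressed in units of the variable's sd; the strong-signal preset uses
  |slope| between 0.3 and 1.2 sd, the zero-signal control sets all slopes to 0
  (features then carry no label information by construction).
* **Site shift.** Each site applies an affine map `x → scale · x + shift` per
  variable (shift ~ 0.15 sd), a global missingness multiplier, its own
  prevalence and label-noise rate. This produces the mean/scale/missingness/
  prevalence heterogeneity a multi-center federation must absorb.
* **Missingness.** Candidate observations on the tick grid are kept with
  probability `observation_rate × missingness_multiplier` (vitals ~0.85–0.9,
  labs ~0.2–0.35 per 30-minute tick), with integer-minute jitter. Thinning
  yields leading gaps and empty hours naturally. Missingness is independent of
  severity and outcome — *informative* (outcome-dependent) missingness is
  deliberately out of scope, so passing tests say nothing about models'
  behavior under MNAR mechanisms in real EHR data.
* **Defaults.** Base prevalence 0.12 (a typical ICU in-hospital mortality
  order of magnitude, not a claim about any specific cohort), 48-hour horizon,
  timestamps in integer minutes with hour `k` covering `[60k, 60k+60)`.

Corruption operators support robustness experiments: event thinning plus
per-variable-rescaled Gaussian noise (`perturb_cohort`), and exact-count label
flipping on a named patient subset (`corrupt_labels`, an involution under a
fixed seed).

## Preprocessing

The pipeline order is fixed: exact-duplicate removal → hourly mean → winsor
clip → missingness mask → forward fill → training-mean imputation → z-score.
Statistics (1st/99th percentiles with linear interpolation between order
statistics, means, sds, imputation values) are fitted on observed training
cells only and applied unchanged to validation/test; a sentinel-poisoning test
verifies no non-train value can move a fitted statistic. Whether winsorization
precedes or follows hourly averaging is a genuine design choice here (clip
after averaging); it is documented, not inferred. Zero-variance variables are
mapped to 0 via an sd floor of 1e-8. Patient-level splits are 70/10/20,
floor-based with the remainder assigned to train.

## Risk model

A post-norm transformer encoder: linear embedding of the hourly feature
vector concatenated with its mask (input dim 2D), fixed sinusoidal positional
encodings, encoder blocks of multi-head self-attention and position-wise
feed-forward with residual connections normalized *after* each sublayer
(post-LN, implemented literally), mean pooling over the 48 steps, and a
2-layer MLP head with sigmoid output. Full preset: embed 128, 4 layers, 8
heads, FFN 256, dropout 0.1, head hidden 128. Test preset for CPU suites:
embed 32, 1 layer, 2 heads, FFN 64.

The model, its gradients, and the AdamW/cosine training loop are implemented
directly in NumPy with hand-written backpropagation. This keeps parameter sets
as plain named float64 arrays — the federation hashes, exchanges and linearly
combines them without framework-specific serialization — and makes runs
bitwise reproducible on a fixed BLAS. Gradient correctness is established by
central-difference checks on every parameter tensor; the analytic
parameter/FLOP counters are verified against independent per-layer hand
computations. The FLOP convention is 2 FLOPs per multiply-accumulate counting
matrix products only (embedding, QKV, score matrix, softmax weighting, output
projection, FFN, classifier); elementwise work is excluded.

Training: binary cross-entropy (no class re-weighting), AdamW (lr 5e-4, weight
decay 1e-4), batch 32, cosine schedule with a 5-epoch linear warm-up reaching
full rate at the start of epoch 5, early stopping on validation AUROC with
patience 15, best-checkpoint evaluation. Weight initialization is fan-in
scaled normal, seeded. Local federated training runs exactly one epoch per
round at constant lr with a fresh optimizer state (stateless update exchange).

## Ledger and governance

* **Ledger.** SHA-256 over a canonical key-sorted JSON serialization; blocks
  chain by previous-block hash with a fixed all-zero genesis pointer; block
  timestamps are simulation-round indices, not wall time. Artifacts (model
  updates, agreements, evidence) live off-chain keyed by digest; transactions
  carry only the digest and scalar metadata, and a schema check rejects any
  array-valued summary entry — the privacy boundary is structural, not
  advisory. Signatures are keyed digests (HMAC-SHA256) per registered node:
  simulation-grade authenticity, not asymmetric cryptography. Consensus is
  single-ledger; forks and networking are out of scope.
* **Stake.** A composite exponential moving average:
  `S ← β S + (1−β) [w_u max(0, c) + w_c compliance + w_r R/max R]` with equal
  default weights, β = 0.9, then clipped to the optional stake cap. The
  contribution utility entering stake is the anomaly-discounted score `c`.
* **Validator sampling.** `P(i) = S_i / Σ_j S_j`; committees are drawn without
  replacement with stake-proportional first-draw probabilities; every
  `rotation_period` rounds the previous committee is excluded when enough
  alternatives exist. All-zero stakes raise a degenerate-stake error.
* **Reputation.** `R ← max(ε, (1−ρ) R + η c)` with ρ = 0.05, η = 1.0,
  ε = 0.05. Negative contributions lower reputation but never below ε, which
  keeps aggregation weights defined and lets a penalized node recover.
* **Contribution scoring.** `c = Δ-validation-AUROC × discount`, where the Δ
  is measured by applying the node's update alone to the previous global
  model, and the discount (0.5) applies when the update's Euclidean norm
  exceeds 5× the median peer norm. The audit is this norm check plus a format
  check (schema and finiteness). These operational definitions of
  "audit-fail" and "anomaly" are declared stand-ins — the framework concept
  does not pin them down.
* **Rewards.** `reward = λ max(0, c) − μ·1[audit fail]`, λ = 1.0, μ = 0.5,
  clipped to ±`reward_cap` (1.0). Balances floor at zero; unenforceable
  penalties are logged as shortfalls, never as debt. Token conservation —
  balance changes equal net on-chain reward events — is asserted to 1e-12 in
  every simulation the suite runs.
* **Agreements.** Contract state machines implement exactly three actions:
  log commitments, verify fulfillment signals (commitment-present,
  metric-threshold, validator-attestation rules), execute reward/penalty at
  settlement. Pools are minted from a treasury at registration; undistributed
  remainders go to the settling validator; settlement is idempotent and
  verdicts are immutable once non-pending. Round rewards and contract rewards
  are separate, jointly conserved token flows.

## Federated round and ablation semantics

Each round: (1) trainers run one local epoch from the current global model;
(2) updates are committed on-chain; (3) a validator is stake-sampled; (4) the
validator audits and scores each update; (5) the new global model is the
reputation-weighted average of audit-passing local parameter sets (weights
`R_i/ΣR_j`; full-parameter averaging equals update averaging when all locals
start from the shared global); (6) reputation, stake and rewards update and
are emitted as transactions; (7) the round record is appended. If no update
passes audit the round aborts with the global model unchanged and the abort
logged on-chain.

The validation split belongs to the validation/aggregation node; the
preprocessor is fitted only on the trainers' pooled training partitions.
Partitions are site-aligned when the cohort has at least as many sites as
trainers, otherwise an even random split; partitioning never reads labels, so
adversarial-label experiments can corrupt a partition computed in advance.

Ablation switches: *w/o collaborative learning* replaces the governance loop
with uniform averaging (no validation, no reputation or stake updates); *w/o
token incentives* stops reward issuance and no longer excludes failed-audit
updates from aggregation (the incentive layer becomes inert); *w/o
privacy-preserving sharing* pools the trainers' raw partitions at the
aggregator and trains centrally for the same epoch budget — the natural
complement of update-only exchange, an interpretation rather than a claim
about the framework's intent. Sensitivity knobs: initial stakes from a
Dirichlet (low concentration α = 5, high α = 0.3), reputation dynamics (ρ, η)
halved/doubled, incentive strength λ ×0.25/×4.

## Problem sizes and statistical protocol

Experiments are sized for a single CPU: learning-sanity runs use a
2000-patient single-site cohort with the reduced architecture; the
adversarial-trainer study uses a 480-patient three-site cohort, 30 rounds,
with one of two trainers holding 40% flipped labels. Robustness follows the
deployment protocol — the pipeline trains on the clean cohort and the
trained model is evaluated on the held-out test episodes with their
measurement stream corrupted (30% event deletion, or 0.5-sd per-variable
rescaled noise). Because the single-latent-factor generator is heavily
over-determined by its 16 redundant channels, these corruptions produce
sub-point AUROC effects; the robustness study therefore runs at a
moderate-signal operating point (slope scale 0.3, clean test AUROC ≈ 0.89)
on a 2500-patient cohort whose 500-patient test split resolves them. Replication follows the mean ± sample-sd
(n−1) protocol over 5 seeds with two-sided paired t-tests on per-seed test
AUROC; the no-signal control is likewise reported as a 5-seed mean because a
single 400-patient test split has a null AUROC sd of ≈ 0.05, which would make
a single-run chance-band check uninformative.

## Known limitations

The generator's AR(1)-plus-latent-severity process exhibits temporal
correlation, missingness and site shift but none of the richer structure of
real EHR (interventions, medication feedback, informative missingness,
non-stationarity); results on it demonstrate that the machinery is correct
and that the governance layer behaves directionally as intended under
adversarial updates — they do not predict absolute performance on real ICU
data. Signatures are symmetric stand-ins; there is no networking, fork
resolution, secure aggregation or differential privacy. The reputation
mechanism defends against persistently harmful updates measurable on a clean
validation set; a poisoned validation set defeats it by construction.
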