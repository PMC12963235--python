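"""Federated consortium orchestration.

Default topology mirrors a small hospital consortium: two data-holding
training nodes and one validation/aggregation node. Each round, trainers run
one local epoch from the current global model and commit their additive
updates on-chain; a stake-sampled validator audits and scores each update by
the validation-AUROC improvement it brings alone; the new global model is
the reputation-weighted average of the audit-passing local models; and
reputation, stake and token rewards are updated and recorded as ledger
transactions. Ablation switches disable the collaborative-learning layer
(uniform averaging, no validation, no reputation), the incentive layer (no
token rewards, failed audits no longer excluded), or privacy-preserving
exchange (raw partitions pooled and trained centrally).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np

from ledgerfed import governance as gov
from ledgerfed import preprocess as prep
from ledgerfed import risk_model as rm
from ledgerfed.cohort import RawCohort, corrupt_labels
from ledgerfed.errors import ConfigurationError
from ledgerfed.evaluation import MetricsReport, compute_report
from ledgerfed.ledger import Ledger


@dataclass
class ConsortiumConfig:
    """Topology and round structure. ``trainer_ids`` hold data partitions;
    exactly one ``validator_id`` owns the validation split by default."""

    trainer_ids: tuple[str, ...] = ("hospital_a", "hospital_b")
    validator_id: str = "coordinator"
    rounds: int = 30
    local_epochs: int = 1
    aggregation: str = "reputation_weighted"  # or "uniform"
    disable_governance: bool = False
    disable_incentives: bool = False
    disable_privacy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation not in ("reputation_weighted", "uniform"):
            raise ConfigurationError("aggregation must be reputation_weighted or uniform")
        if self.rounds < 0 or self.local_epochs < 0:
            raise ConfigurationError("rounds and local_epochs must be nonnegative")


@dataclass
class RoundRecord:
    """Complete audit trail of one federated round."""

    round: int
    update_digests: dict[str, str]
    validator_ids: list[str]
    contribution_scores: dict[str, float]
    raw_delta_auroc: dict[str, float]
    audit_pass: dict[str, bool]
    rewards: dict[str, float]
    aggregation_weights: dict[str, float]
    global_digest: str
    val_auroc_before: float
    val_auroc_after: float
    aborted: bool = False

    def as_dict(self) -> dict:
        return dict(round=self.round, update_digests=self.update_digests,
                    validator_ids=self.validator_ids,
                    contribution_scores=self.contribution_scores,
                    raw_delta_auroc=self.raw_delta_auroc,
                    audit_pass=self.audit_pass, rewards=self.rewards,
                    aggregation_weights=self.aggregation_weights,
                    global_digest=self.global_digest,
                    val_auroc_before=self.val_auroc_before,
                    val_auroc_after=self.val_auroc_after, aborted=self.aborted)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class SimulationResult:
    final_params: rm.ModelParams
    records: list[RoundRecord]
    ledger: Ledger
    nodes: dict[str, gov.NodeState]
    metrics: MetricsReport
    split_digest: str
    token_shortfalls: float = 0.0
    # evaluation context: fitted preprocessor, variable order, test patient
    # ids and model config, so drivers can re-evaluate the trained model on
    # alternative versions of the held-out data
    context: dict | None = None


def _round_seed(base: int, round_: int, salt: int = 0) -> int:
    return int((base * 1_000_003 + round_ * 10_007 + salt * 101 + 7) % (2 ** 31))


def trainer_partition(cohort: RawCohort, trainer_ids: tuple[str, ...],
                      seed: int) -> dict[str, list[str]]:
    """Assign train-split patients to trainers, site-aligned when the cohort
    has at least as many sites as trainers, otherwise an even random split.

    Deterministic in the cohort's patient ids and the seed; never reads
    labels, so experiment drivers can corrupt a partition after computing it.
    """
    eligible, _ = prep.filter_eligible(cohort)
    split = prep.split_cohort(eligible.patient_ids(), seed=seed)
    train_ids = sorted(split.patients("train"))
    site_of = dict(zip(eligible.measurements["patient_id"], eligible.measurements["site_id"]))
    sites = sorted({site_of.get(p, "") for p in train_ids})
    partition: dict[str, list[str]] = {t: [] for t in trainer_ids}
    if len(sites) >= len(trainer_ids):
        for i, s in enumerate(sites):
            t = trainer_ids[i % len(trainer_ids)]
            partition[t].extend(p for p in train_ids if site_of.get(p, "") == s)
    else:
        rng = np.random.default_rng(_round_seed(seed, 0, 999))
        order = rng.permutation(len(train_ids))
        for rank, idx in enumerate(order):
            partition[trainer_ids[rank % len(trainer_ids)]].append(train_ids[idx])
    for t in partition:
        partition[t] = sorted(partition[t])
    return partition


def _prepare_episodes(cohort: RawCohort, config: ConsortiumConfig):
    """Filter, split, grid, fit the preprocessor on the trainers' pooled
    training data only, and transform every split."""
    eligible, _ = prep.filter_eligible(cohort)
    split = prep.split_cohort(eligible.patient_ids(), seed=config.seed)
    variable_ids = sorted(eligible.measurements["variable_id"].unique())
    episodes = prep.hourly_aggregate(eligible, variable_ids)
    by_id = {e.patient_id: e for e in episodes}

    partition = trainer_partition(cohort, config.trainer_ids, config.seed)
    seen: set[str] = set()
    for ids in partition.values():
        overlap = seen & set(ids)
        if overlap:
            raise ConfigurationError(f"partition overlap at patients {sorted(overlap)[:3]}")
        seen |= set(ids)

    train_grid = [by_id[p] for ids in partition.values() for p in ids]
    state = prep.fit_preprocessor(train_grid, variable_ids)
    trainer_eps = {t: prep.transform(state, [by_id[p] for p in ids])
                   for t, ids in partition.items()}
    val_eps = prep.transform(state, [by_id[p] for p in sorted(split.patients("val"))])
    test_eps = prep.transform(state, [by_id[p] for p in sorted(split.patients("test"))])

    split_digest = hashlib.sha256(json.dumps(
        sorted(split.assignment.items())).encode()).hexdigest()
    return trainer_eps, val_eps, test_eps, variable_ids, split_digest, state, split


def aggregate_params(locals_: dict[str, rm.ModelParams],
                     weights: dict[str, float]) -> rm.ModelParams:
    """Weighted average of full local parameter sets; weights must sum to 1."""
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError("aggregation weights must sum to 1")
    ids = sorted(weights)
    return rm.ModelParams.combine([locals_[i] for i in ids], [weights[i] for i in ids])


def run_round(round_: int, global_params: rm.ModelParams, trainer_eps, val_eps,
              nodes: dict[str, gov.NodeState], ledger: Ledger,
              config: ConsortiumConfig, gconfig: gov.GovernanceConfig,
              mconfig: rm.ModelConfig, tconfig: rm.TrainConfig,
              prev_committee: list[str] | None = None
              ) -> tuple[rm.ModelParams, RoundRecord, list[str], float]:
    """Execute one federated round; returns (new global, record, committee,
    token shortfall incurred this round)."""
    from ledgerfed.evaluation import auroc

    trainers = list(config.trainer_ids)
    txs = []

    # (1) local training + (2) on-chain commitments
    locals_: dict[str, rm.ModelParams] = {}
    updates: dict[str, rm.ModelParams] = {}
    update_digests: dict[str, str] = {}
    for i, t in enumerate(trainers):
        local_tc = replace(tconfig, seed=_round_seed(config.seed, round_, i))
        new_params, update = rm.train_local(global_params, trainer_eps[t], mconfig,
                                            local_tc, epochs=config.local_epochs)
        locals_[t] = new_params
        updates[t] = update
        tx = ledger.record_commitment(t, update.to_bytes(), "update_commitment", round_,
                                      summary=dict(node_id=t, update_norm=update.norm()),
                                      append=False)
        txs.append(tx)
        update_digests[t] = tx.payload_digest
        nodes[t].compliance["timely_submissions"] += 1

    Xval, yval = rm.episodes_to_arrays(val_eps)
    val_before = auroc(yval, rm.forward(global_params, mconfig, Xval))

    # (3) PoS validator (committee) selection among validator-role nodes
    validator_pool = [n for n in nodes.values() if n.role == "validator_aggregator"]
    if config.disable_governance or not validator_pool:
        committee = [config.validator_id]
    else:
        committee = gov.sample_committee(validator_pool, gconfig, round_,
                                         _round_seed(config.seed, round_, 500),
                                         previous_committee=prev_committee)

    # (4) audit + contribution scoring
    scores: dict[str, gov.ContributionScore] = {}
    if not config.disable_governance:
        peer_norms = [updates[t].norm() for t in trainers]
        for t in trainers:
            scores[t] = gov.score_contribution(global_params, updates[t], peer_norms,
                                               val_eps, mconfig, gconfig,
                                               node_id=t, round_=round_)
            txs.append(ledger.make_transaction(
                committee[0], "audit_result", update_digests[t],
                dict(node_id=t, audit_pass=scores[t].audit_pass,
                     raw_delta_auroc=scores[t].raw_delta_auroc,
                     discount=scores[t].discount), round_))
            if scores[t].audit_pass:
                nodes[t].compliance["audit_passes"] += 1
            else:
                nodes[t].compliance["audit_failures"] += 1
    else:
        scores = {t: gov.ContributionScore(t, round_, 0.0, 1.0, True) for t in trainers}

    # (5) aggregation
    uniform = config.disable_governance or config.aggregation == "uniform"
    if uniform:
        included = trainers
    elif config.disable_incentives:
        included = trainers  # incentive layer inert: no exclusion
    else:
        included = [t for t in trainers if scores[t].audit_pass]

    aborted = len(included) == 0
    if aborted:
        new_global = global_params
        weights = {}
        txs.append(ledger.make_transaction(
            committee[0], "audit_result", "0" * 64,
            dict(event="round_abort", reason="no audit-passing update"), round_))
    else:
        if uniform:
            weights = {t: 1.0 / len(included) for t in included}
        else:
            reps = np.array([nodes[t].reputation for t in included])
            weights = {t: float(r / reps.sum()) for t, r in zip(included, reps)}
        new_global = aggregate_params({t: locals_[t] for t in included}, weights)

    val_after = auroc(yval, rm.forward(new_global, mconfig, Xval))

    # (6) reputation, stake, token rewards
    rewards: dict[str, float] = {}
    shortfall_total = 0.0
    for t in trainers:
        sc = scores[t]
        if not config.disable_governance:
            nodes[t] = gov.update_reputation(nodes[t], sc.c, gconfig)
            max_rep = max(n.reputation for n in nodes.values())
            nodes[t] = gov.update_stake(nodes[t], sc.c, nodes[t].compliance_score(),
                                        gconfig, max_reputation=max_rep)
            txs.append(ledger.make_transaction(
                config.validator_id, "reputation_state", "0" * 64,
                dict(node_id=t, reputation=nodes[t].reputation), round_))
            txs.append(ledger.make_transaction(
                config.validator_id, "stake_state", "0" * 64,
                dict(node_id=t, stake=nodes[t].stake), round_))
        if config.disable_incentives:
            rewards[t] = 0.0
        else:
            reward = gov.compute_reward(sc.c, sc.audit_pass, gconfig)
            nodes[t], applied, short = gov.apply_reward(nodes[t], reward)
            shortfall_total += short
            rewards[t] = applied
            txs.append(ledger.make_transaction(
                config.validator_id, "reward_event", "0" * 64,
                dict(node_id=t, applied_amount=applied, nominal_amount=reward,
                     shortfall=short), round_))

    # (7) commit new global + append the round block
    gtx = ledger.record_commitment(committee[0], new_global.to_bytes(),
                                   "update_commitment", round_,
                                   summary=dict(node_id=committee[0], artifact="global_model"),
                                   append=False)
    txs.append(gtx)
    ledger.append_block(txs, timestamp=round_)

    record = RoundRecord(
        round=round_,
        update_digests=update_digests,
        validator_ids=committee,
        contribution_scores={t: scores[t].c for t in trainers},
        raw_delta_auroc={t: scores[t].raw_delta_auroc for t in trainers},
        audit_pass={t: scores[t].audit_pass for t in trainers},
        rewards=rewards,
        aggregation_weights=weights,
        global_digest=new_global.digest(),
        val_auroc_before=float(val_before),
        val_auroc_after=float(val_after),
        aborted=aborted,
    )
    return new_global, record, committee, shortfall_total


def run_simulation(cohort: RawCohort, config: ConsortiumConfig,
                   gconfig: gov.GovernanceConfig | None = None,
                   mconfig: rm.ModelConfig | None = None,
                   tconfig: rm.TrainConfig | None = None,
                   initial_stakes: dict[str, float] | None = None
                   ) -> SimulationResult:
    """Run the full federated simulation and evaluate on the held-out test
    split; fully reproducible under ``config.seed``."""
    gconfig = gconfig or gov.GovernanceConfig()
    (trainer_eps, val_eps, test_eps, variable_ids, split_digest,
     prep_state, split) = _prepare_episodes(cohort, config)
    D = len(variable_ids)
    mconfig = mconfig or rm.test_preset(2 * D)
    tconfig = tconfig or rm.TrainConfig(seed=config.seed)
    context = dict(preprocessor=prep_state, variable_ids=variable_ids,
                   test_patient_ids=sorted(split.patients("test")),
                   model_config=mconfig)

    ledger = Ledger()
    for t in config.trainer_ids:
        ledger.register_node(t, seed=config.seed)
    ledger.register_node(config.validator_id, seed=config.seed)

    nodes = {t: gov.NodeState(t, role="trainer") for t in config.trainer_ids}
    nodes[config.validator_id] = gov.NodeState(config.validator_id, role="validator_aggregator")
    if initial_stakes:
        for nid, s in initial_stakes.items():
            if nid in nodes:
                nodes[nid] = replace(nodes[nid], stake=float(s))

    if config.disable_privacy:
        # pooled-raw-data centralized training: the natural complement of
        # update-only exchange
        pooled = [e for t in config.trainer_ids for e in trainer_eps[t]]
        central_tc = replace(tconfig, seed=config.seed,
                             max_epochs=max(config.rounds * config.local_epochs, 2),
                             patience=max(min(tconfig.patience,
                                              config.rounds * config.local_epochs - 1), 1))
        params, _history = rm.train_centralized(pooled, val_eps, mconfig, central_tc)
        probs = rm.forward(params, mconfig, rm.episodes_to_arrays(test_eps)[0])
        ytest = np.array([e.y for e in test_eps])
        metrics = compute_report(ytest, probs, seed=config.seed)
        return SimulationResult(params, [], ledger, nodes, metrics, split_digest,
                                context=context)

    global_params = rm.init_model(mconfig, seed=config.seed)
    records: list[RoundRecord] = []
    committee: list[str] | None = None
    shortfalls = 0.0
    for r in range(config.rounds):
        global_params, record, committee, short = run_round(
            r, global_params, trainer_eps, val_eps, nodes, ledger,
            config, gconfig, mconfig, tconfig, prev_committee=committee)
        records.append(record)
        shortfalls += short

    probs = rm.forward(global_params, mconfig, rm.episodes_to_arrays(test_eps)[0])
    ytest = np.array([e.y for e in test_eps])
    metrics = compute_report(ytest, probs, seed=config.seed)
    return SimulationResult(global_params, records, ledger, nodes, metrics,
                            split_digest, token_shortfalls=shortfalls,
                            context=context)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "disable_privacy", "disable_governance", "disable_incentives")


def _variant_config(base: ConsortiumConfig, variant: str, seed: int) -> ConsortiumConfig:
    kwargs = dict(disable_governance=False, disable_incentives=False, disable_privacy=False)
    if variant != "full":
        kwargs[variant] = True
    return replace(base, seed=seed, **kwargs)


def run_ablation(cohort: RawCohort, base: ConsortiumConfig, seeds: list[int],
                 gconfig: gov.GovernanceConfig | None = None,
                 mconfig: rm.ModelConfig | None = None,
                 tconfig: rm.TrainConfig | None = None,
                 corrupt_trainer: str | None = None,
                 flip_fraction: float = 0.0,
                 variants: tuple[str, ...] = ABLATION_VARIANTS) -> dict[str, dict]:
    """Evaluate {full, w/o privacy, w/o collaborative learning, w/o token
    incentives} under shared seeds; optionally corrupt one trainer's labels
    first (adversarial-node setting).

    Returns per-variant {metric: (mean, sd), 'reports': [...], 'split_digests': [...]}.
    """
    from ledgerfed.evaluation import aggregate_runs

    out: dict[str, dict] = {}
    for variant in variants:
        reports, digests = [], []
        for seed in seeds:
            cfg = _variant_config(base, variant, seed)
            data = cohort
            if corrupt_trainer and flip_fraction > 0:
                part = trainer_partition(cohort, cfg.trainer_ids, seed)
                data = corrupt_labels(cohort, part[corrupt_trainer], flip_fraction,
                                      seed=_round_seed(seed, 0, 42))
            res = run_simulation(data, cfg, gconfig, mconfig, tconfig)
            reports.append(res.metrics)
            digests.append(res.split_digest)
        stats = aggregate_runs(reports) if len(reports) >= 2 else {}
        out[variant] = dict(stats, reports=reports, split_digests=digests)
    return out


SENSITIVITY_SETTINGS = (
    "default",
    "stake_low_concentration",
    "stake_high_concentration",
    "reputation_slow",
    "reputation_fast",
    "incentive_low",
    "incentive_high",
)


def run_sensitivity(cohort: RawCohort, base: ConsortiumConfig, seeds: list[int],
                    gconfig: gov.GovernanceConfig | None = None,
                    mconfig: rm.ModelConfig | None = None,
                    tconfig: rm.TrainConfig | None = None) -> dict[str, dict]:
    """Sweep the documented knob mappings with shared seeds: initial stakes
    from a Dirichlet (low concentration alpha=5, high alpha=0.3), reputation
    dynamics (rho, eta) halved/doubled, incentive strength lambda x0.25/x4."""
    from ledgerfed.evaluation import aggregate_runs

    gconfig = gconfig or gov.GovernanceConfig()
    out: dict[str, dict] = {}
    n_nodes = len(base.trainer_ids) + 1
    for setting in SENSITIVITY_SETTINGS:
        reports = []
        for seed in seeds:
            g = gconfig
            stakes = None
            if setting == "stake_low_concentration":
                alpha = 5.0
            elif setting == "stake_high_concentration":
                alpha = 0.3
            else:
                alpha = None
            if alpha is not None:
                rng = np.random.default_rng(_round_seed(seed, 1, 77))
                draw = rng.dirichlet([alpha] * n_nodes) * n_nodes
                ids = list(base.trainer_ids) + [base.validator_id]
                stakes = dict(zip(ids, draw))
            if setting == "reputation_slow":
                g = replace(gconfig, reputation_decay=gconfig.reputation_decay * 0.5,
                            reputation_gain=gconfig.reputation_gain * 0.5)
            elif setting == "reputation_fast":
                g = replace(gconfig, reputation_decay=min(gconfig.reputation_decay * 2, 0.9),
                            reputation_gain=gconfig.reputation_gain * 2)
            elif setting == "incentive_low":
                g = replace(gconfig, lam=gconfig.lam * 0.25)
            elif setting == "incentive_high":
                g = replace(gconfig, lam=gconfig.lam * 4.0)
            res = run_simulation(cohort, replace(base, seed=seed), g, mconfig, tconfig,
                                 initial_stakes=stakes)
            reports.append(res.metrics)
        stats = aggregate_runs(reports) if len(reports) >= 2 else {}
        out[setting] = dict(stats, reports=reports)
    return out


def evaluate_on_cohort(res: SimulationResult, cohort: RawCohort,
                       patient_ids: list[str]) -> MetricsReport:
    """Re-evaluate a trained simulation result on the named patients' data
    from ``cohort``, using the run's own fitted preprocessor."""
    ctx = res.context
    sub = cohort.copy()
    keep = set(patient_ids)
    sub.measurements = sub.measurements[sub.measurements["patient_id"].isin(keep)].reset_index(drop=True)
    sub.outcomes = sub.outcomes[sub.outcomes["patient_id"].isin(keep)].reset_index(drop=True)
    episodes = prep.hourly_aggregate(sub, ctx["variable_ids"])
    tensors = prep.transform(ctx["preprocessor"], episodes)
    probs = rm.forward(res.final_params, ctx["model_config"],
                       rm.episodes_to_arrays(tensors)[0])
    return compute_report([e.y for e in tensors], probs, seed=res.metrics.seed)


def run_robustness(cohort: RawCohort, base: ConsortiumConfig, seeds: list[int],
                   extra_missingness: float = 0.3, noise_sd: float = 0.5,
                   gconfig: gov.GovernanceConfig | None = None,
                   mconfig: rm.ModelConfig | None = None,
                   tconfig: rm.TrainConfig | None = None) -> dict[str, dict]:
    """Deployment-time robustness: train the full pipeline on the clean
    cohort, then evaluate the trained global model on the held-out test
    episodes with their measurement stream corrupted (event thinning or
    added noise). Training, validation and the fitted preprocessor never see
    the corruption, so the measured drop isolates evaluation-time
    degradation."""
    from ledgerfed.cohort import perturb_cohort
    from ledgerfed.evaluation import aggregate_runs

    conditions = {
        "unperturbed": lambda c, s: c,
        "extra_missingness": lambda c, s: perturb_cohort(c, extra_missingness, 0.0, seed=s),
        "added_noise": lambda c, s: perturb_cohort(c, 0.0, noise_sd, seed=s),
    }
    reports: dict[str, list[MetricsReport]] = {name: [] for name in conditions}
    for seed in seeds:
        res = run_simulation(cohort, replace(base, seed=seed), gconfig, mconfig, tconfig)
        test_ids = res.context["test_patient_ids"]
        for name, fn in conditions.items():
            data = fn(cohort, _round_seed(seed, 2, 13))
            reports[name].append(evaluate_on_cohort(res, data, test_ids))
    out: dict[str, dict] = {}
    for name, reps in reports.items():
        stats = aggregate_runs(reps) if len(reps) >= 2 else {}
        out[name] = dict(stats, reports=reps)
    return out
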