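"""Modified proof-of-stake consensus and the token incentive layer.

Stake is a composite exponential moving average of contribution utility,
protocol compliance and normalized reputation, optionally capped to prevent
persistent dominance. Validators are sampled with probability proportional
to stake, S_i / sum_j S_j, with committee draws without replacement and
periodic rotation excluding the previous committee. Contribution scores are
anomaly-discounted validation-AUROC improvements; token rewards follow
reward = lambda * max(0, c) - mu * 1[audit fail], clipped to the reward cap,
with balances floored at zero (shortfalls logged, never enforced as debt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ledgerfed.errors import (
    ConfigurationError,
    DegenerateStakeError,
    SamplingError,
    ScoringError,
)


@dataclass
class GovernanceConfig:
    ema_beta: float = 0.9
    stake_cap: float | None = None
    reputation_decay: float = 0.05   # rho
    reputation_gain: float = 1.0     # eta
    reputation_floor: float = 0.05   # epsilon
    lam: float = 1.0                 # incentive strength
    mu: float = 0.5                  # audit-fail penalty
    reward_cap: float = 1.0
    committee_size: int = 1
    rotation_period: int = 1
    anomaly_norm_threshold: float = 5.0   # multiple of median peer norm
    anomaly_discount: float = 0.5
    # composite-stake weights (utility, compliance, reputation); equal thirds
    stake_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not 0 < self.ema_beta < 1:
            raise ConfigurationError("ema_beta must be in (0, 1)")
        if not 0 <= self.reputation_decay < 1:
            raise ConfigurationError("reputation_decay must be in [0, 1)")
        if self.reputation_gain <= 0 or self.reputation_floor <= 0:
            raise ConfigurationError("reputation gain and floor must be positive")
        if self.lam < 0 or self.mu < 0:
            raise ConfigurationError("lambda and mu must be nonnegative")
        if not 0 <= self.anomaly_discount <= 1:
            raise ConfigurationError("anomaly_discount must be in [0, 1]")
        if self.committee_size < 1 or self.rotation_period < 1:
            raise ConfigurationError("committee_size and rotation_period must be >= 1")


@dataclass
class NodeState:
    node_id: str
    role: str = "trainer"  # or "validator_aggregator"
    stake: float = 1.0
    reputation: float = 1.0
    tokens: float = 0.0
    compliance: dict = field(default_factory=lambda: dict(
        timely_submissions=0, format_failures=0, audit_passes=0, audit_failures=0))

    def compliance_score(self) -> float:
        """Fraction of clean interactions in the compliance record; 1.0 when
        no history exists yet."""
        good = self.compliance["timely_submissions"] + self.compliance["audit_passes"]
        bad = self.compliance["format_failures"] + self.compliance["audit_failures"]
        total = good + bad
        return 1.0 if total == 0 else good / total


@dataclass
class ContributionScore:
    node_id: str
    round: int
    raw_delta_auroc: float
    discount: float
    audit_pass: bool

    @property
    def c(self) -> float:
        return self.raw_delta_auroc * self.discount


def selection_probabilities(nodes: list[NodeState]) -> dict[str, float]:
    """Stake-proportional selection: P(i) = S_i / sum_j S_j."""
    stakes = np.array([n.stake for n in nodes], dtype=float)
    total = stakes.sum()
    if total <= 0:
        raise DegenerateStakeError("all stakes are zero")
    return {n.node_id: float(s / total) for n, s in zip(nodes, stakes)}


def sample_committee(nodes: list[NodeState], config: GovernanceConfig,
                     round_: int, seed: int,
                     previous_committee: list[str] | None = None) -> list[str]:
    """Draw ``committee_size`` distinct validators without replacement with
    first-draw probabilities proportional to stake.

    On rotation rounds (every ``rotation_period`` rounds) the previous
    committee is excluded from the draw when enough alternatives remain.
    """
    eligible = list(nodes)
    rotate = previous_committee and config.rotation_period > 0 and round_ % config.rotation_period == 0
    if rotate:
        fresh = [n for n in eligible if n.node_id not in set(previous_committee)]
        if len(fresh) >= config.committee_size:
            eligible = fresh
    if len(eligible) < config.committee_size:
        raise SamplingError(
            f"need {config.committee_size} eligible validators, have {len(eligible)}"
        )
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    pool = list(eligible)
    for _ in range(config.committee_size):
        probs = selection_probabilities(pool)
        ids = [n.node_id for n in pool]
        p = np.array([probs[i] for i in ids])
        pick = rng.choice(len(ids), p=p)
        chosen.append(ids[pick])
        pool = [n for n in pool if n.node_id != ids[pick]]
    return chosen


def update_stake(node: NodeState, contribution_utility: float,
                 compliance_score: float, config: GovernanceConfig,
                 max_reputation: float = 1.0) -> NodeState:
    """Composite EMA stake update followed by the optional cap.

    instantaneous = w_u*max(0,utility) + w_c*compliance + w_r*(R/max R);
    S_new = beta*S_old + (1-beta)*instantaneous, clipped to the cap.
    """
    w_u, w_c, w_r = config.stake_weights
    rep_norm = node.reputation / max(max_reputation, 1e-12)
    composite = (w_u * max(0.0, contribution_utility)
                 + w_c * compliance_score
                 + w_r * rep_norm)
    new_stake = config.ema_beta * node.stake + (1.0 - config.ema_beta) * composite
    if config.stake_cap is not None:
        new_stake = min(new_stake, config.stake_cap)
    return replace(node, stake=max(0.0, new_stake))


def update_reputation(node: NodeState, c: float, config: GovernanceConfig) -> NodeState:
    """R_new = max(floor, (1-rho)*R_old + eta*c)."""
    new_rep = max(config.reputation_floor,
                  (1.0 - config.reputation_decay) * node.reputation
                  + config.reputation_gain * c)
    return replace(node, reputation=new_rep)


def score_contribution(prev_global, node_update, peer_norms: list[float],
                       val_episodes, model_config, config: GovernanceConfig,
                       node_id: str, round_: int) -> ContributionScore:
    """Anomaly-discounted validation-AUROC improvement of one update applied
    alone to the previous global model.

    The audit is a format check (schema match, finite entries) AND a norm
    check (update norm within ``anomaly_norm_threshold`` times the median
    peer norm). A failed norm check applies the anomaly discount.
    """
    from ledgerfed.evaluation import auroc
    from ledgerfed.risk_model import episodes_to_arrays, forward

    if not val_episodes:
        raise ScoringError("validation set is empty")
    Xval, yval = episodes_to_arrays(val_episodes)
    if len(np.unique(yval)) < 2:
        raise ScoringError("validation AUROC undefined on single-class set")

    format_ok = prev_global.same_schema(node_update) and all(
        np.all(np.isfinite(v)) for v in node_update.tensors.values()
    )
    norm = node_update.norm()
    median_peer = float(np.median(peer_norms)) if peer_norms else norm
    norm_ok = (median_peer == 0) or (norm <= config.anomaly_norm_threshold * max(median_peer, 1e-12))

    if not format_ok:
        return ContributionScore(node_id, round_, 0.0, 0.0, False)

    base = auroc(yval, forward(prev_global, model_config, Xval))
    candidate = prev_global + node_update
    raw_delta = auroc(yval, forward(candidate, model_config, Xval)) - base
    discount = 1.0 if norm_ok else config.anomaly_discount
    return ContributionScore(node_id, round_, float(raw_delta), discount, bool(norm_ok))


def compute_reward(c: float, audit_pass: bool, config: GovernanceConfig) -> float:
    """Token reward: lambda*max(0, c) - mu*1[audit fail], clipped to the cap."""
    reward = config.lam * max(0.0, c) - config.mu * (0.0 if audit_pass else 1.0)
    return float(np.clip(reward, -config.reward_cap, config.reward_cap))


def apply_reward(node: NodeState, reward: float) -> tuple[NodeState, float, float]:
    """Apply a signed reward to the balance, flooring at zero.

    Returns (new state, applied amount, unenforced shortfall)."""
    new_balance = node.tokens + reward
    shortfall = 0.0
    if new_balance < 0:
        shortfall = -new_balance
        new_balance = 0.0
    applied = new_balance - node.tokens
    return replace(node, tokens=new_balance), float(applied), float(shortfall)
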