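"""Deterministic smart-contract agreement engine.

Agreements are ledger-backed state machines implementing exactly three
actions: log commitments, verify fulfillment signals, and execute
reward/penalty actions at settlement. The rule grammar covers three
evaluation rules — a commitment being present, an attested metric meeting a
threshold, and a validator attestation — which is sufficient for the
curriculum/deliverable-style obligations the consortium records.

Reward pools are minted from a configured treasury at registration and
recorded on-chain; at settlement each participant whose obligations are all
fulfilled receives pool * share, responsible nodes of missed obligations are
charged the per-miss penalty (floored at zero balance, shortfall logged),
and any undistributed remainder is paid to the settling validator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ledgerfed.errors import LookupError_, RegistrationError, StateError
from ledgerfed.governance import NodeState, apply_reward
from ledgerfed.ledger import Ledger

SHARE_TOL = 1e-12


@dataclass
class Obligation:
    obligation_id: str
    responsible: str
    deadline_round: int
    # rule: ("commitment_present",) | ("metric_threshold", metric, threshold)
    #       | ("validator_attestation",)
    evaluation_rule: tuple

    def __post_init__(self) -> None:
        if self.deadline_round <= 0:
            raise RegistrationError("deadlines must be strictly positive")
        if self.evaluation_rule[0] not in (
            "commitment_present", "metric_threshold", "validator_attestation"
        ):
            raise RegistrationError(f"unknown evaluation rule {self.evaluation_rule[0]}")


@dataclass
class Agreement:
    agreement_id: str
    participants: tuple[str, ...]
    obligations: list[Obligation]
    reward_distribution: dict[str, float]
    reward_pool: float
    penalty_per_miss: float = 0.0
    status: str = "active"

    def __post_init__(self) -> None:
        shares = np.array(list(self.reward_distribution.values()), dtype=float)
        if (shares < 0).any() or abs(shares.sum() - 1.0) > SHARE_TOL:
            raise RegistrationError("shares must be nonnegative and sum to 1")
        if self.penalty_per_miss < 0 or self.reward_pool < 0:
            raise RegistrationError("pool and penalty must be nonnegative")


@dataclass
class ObligationEvent:
    agreement_id: str
    obligation_id: str
    round: int
    evidence_digest: str
    verdict: str  # fulfilled | missed | pending


class ContractEngine:
    """Holds the live agreements and executes their lifecycle on the ledger."""

    def __init__(self, ledger: Ledger, treasury_node: str = "treasury") -> None:
        self.ledger = ledger
        self.treasury = treasury_node
        if not ledger.is_registered(treasury_node):
            ledger.register_node(treasury_node)
        self.agreements: dict[str, Agreement] = {}
        self.verdicts: dict[tuple[str, str], ObligationEvent] = {}
        self.settlement_log: list[dict] = []

    def register_agreement(self, agreement: Agreement, round_: int = 0):
        """Serialize, commit on-chain, mint the reward pool, set active."""
        if agreement.agreement_id in self.agreements:
            raise RegistrationError(f"duplicate agreement_id {agreement.agreement_id}")
        unknown = [p for p in agreement.participants if not self.ledger.is_registered(p)]
        if unknown:
            raise RegistrationError(f"unknown participants: {unknown}")
        blob = json.dumps(dict(
            agreement_id=agreement.agreement_id,
            participants=list(agreement.participants),
            obligations=[(o.obligation_id, o.responsible, o.deadline_round,
                          list(o.evaluation_rule)) for o in agreement.obligations],
            reward_distribution=agreement.reward_distribution,
            reward_pool=agreement.reward_pool,
            penalty_per_miss=agreement.penalty_per_miss,
        ), sort_keys=True).encode()
        tx = self.ledger.record_commitment(
            self.treasury, blob, "agreement_event", round_,
            summary=dict(agreement_id=agreement.agreement_id, event="registered",
                         pool_minted=agreement.reward_pool))
        self.agreements[agreement.agreement_id] = agreement
        for ob in agreement.obligations:
            self.verdicts[(agreement.agreement_id, ob.obligation_id)] = ObligationEvent(
                agreement.agreement_id, ob.obligation_id, round_, "", "pending")
        return tx

    def _get(self, agreement_id: str) -> Agreement:
        if agreement_id not in self.agreements:
            raise LookupError_(f"unknown agreement {agreement_id}")
        return self.agreements[agreement_id]

    def post_fulfillment(self, agreement_id: str, obligation_id: str,
                         evidence: bytes, round_: int,
                         attested_metric: float | None = None,
                         validator_signed: bool = False) -> ObligationEvent:
        """Commit evidence and evaluate the obligation's rule at posting.

        The verdict becomes ``fulfilled`` when the rule holds and the posting
        round is within the deadline; otherwise it stays ``pending`` until
        settlement marks it missed.
        """
        ag = self._get(agreement_id)
        if ag.status == "settled":
            raise StateError(f"agreement {agreement_id} already settled")
        key = (agreement_id, obligation_id)
        if key not in self.verdicts:
            raise LookupError_(f"unknown obligation {obligation_id}")
        event = self.verdicts[key]
        if event.verdict != "pending":
            return event  # verdicts are immutable once non-pending
        ob = next(o for o in ag.obligations if o.obligation_id == obligation_id)

        tx = self.ledger.record_commitment(
            ob.responsible if self.ledger.is_registered(ob.responsible) else self.treasury,
            evidence, "agreement_event", round_,
            summary=dict(agreement_id=agreement_id, obligation_id=obligation_id,
                         event="evidence"))

        rule = ob.evaluation_rule
        holds = False
        if rule[0] == "commitment_present":
            holds = True
        elif rule[0] == "metric_threshold":
            holds = attested_metric is not None and attested_metric >= rule[2]
        elif rule[0] == "validator_attestation":
            holds = validator_signed
        verdict = "fulfilled" if (holds and round_ <= ob.deadline_round) else "pending"
        self.verdicts[key] = ObligationEvent(agreement_id, obligation_id, round_,
                                             tx.payload_digest, verdict)
        return self.verdicts[key]

    def settle(self, agreement_id: str, current_round: int,
               nodes: dict[str, NodeState], validator_id: str | None = None) -> list[dict]:
        """Execute reward/penalty actions once all deadlines have passed.

        Pending obligations become missed; fulfilled-only participants get
        pool * share; responsible nodes of missed obligations pay the per-miss
        penalty (balance floored at 0, shortfall logged); the undistributed
        remainder goes to the settling validator (or back to the treasury).
        Idempotent: a second call emits nothing.
        """
        ag = self._get(agreement_id)
        if ag.status == "settled":
            return []
        if any(current_round <= o.deadline_round for o in ag.obligations):
            raise StateError("cannot settle before all deadlines have passed")

        transfers: list[dict] = []
        for ob in ag.obligations:
            key = (agreement_id, ob.obligation_id)
            if self.verdicts[key].verdict == "pending":
                ev = self.verdicts[key]
                self.verdicts[key] = ObligationEvent(ev.agreement_id, ev.obligation_id,
                                                     current_round, ev.evidence_digest, "missed")

        def obligations_of(pid: str) -> list[Obligation]:
            return [o for o in ag.obligations if o.responsible == pid]

        distributed = 0.0
        for pid in ag.participants:
            own = obligations_of(pid)
            all_ok = all(self.verdicts[(agreement_id, o.obligation_id)].verdict == "fulfilled"
                         for o in own)
            share = ag.reward_distribution.get(pid, 0.0)
            if all_ok and share > 0:
                amount = ag.reward_pool * share
                applied = amount
                if pid in nodes:
                    nodes[pid], applied, _ = apply_reward(nodes[pid], amount)
                transfers.append(dict(node_id=pid, amount=amount, applied=applied,
                                      reason="agreement_reward"))
                distributed += amount
            for o in own:
                if self.verdicts[(agreement_id, o.obligation_id)].verdict == "missed" \
                        and ag.penalty_per_miss > 0:
                    shortfall = 0.0
                    applied = -ag.penalty_per_miss
                    if pid in nodes:
                        nodes[pid], applied, shortfall = apply_reward(nodes[pid], -ag.penalty_per_miss)
                    transfers.append(dict(node_id=pid, amount=-ag.penalty_per_miss,
                                          applied=applied, reason="missed_obligation",
                                          shortfall=shortfall))

        remainder = ag.reward_pool - distributed
        if remainder > SHARE_TOL:
            target = validator_id or self.treasury
            applied = remainder
            if target in nodes:
                nodes[target], applied, _ = apply_reward(nodes[target], remainder)
            transfers.append(dict(node_id=target, amount=remainder, applied=applied,
                                  reason="remainder"))

        for tr in transfers:
            tx = self.ledger.make_transaction(
                self.treasury, "reward_event", "0" * 64,
                dict(agreement_id=agreement_id, node_id=tr["node_id"],
                     applied_amount=tr["applied"], nominal_amount=tr["amount"],
                     reason=tr["reason"]),
                current_round)
            self.ledger.append_block([tx], timestamp=current_round)
        ag.status = "settled"
        self.settlement_log.append(dict(agreement_id=agreement_id, round=current_round,
                                        transfers=transfers))
        return transfers
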