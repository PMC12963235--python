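"""Simulated permissioned blockchain backing the consortium.

Hash-chained blocks of signed transactions with a hybrid on-/off-chain
layout: bulky artifacts (model updates, agreements, evidence) live in an
off-chain store keyed by SHA-256 digest, while transactions carry only the
digest plus scalar metadata. Authenticity is simulation-grade: each
registered node holds a secret key and signs with a keyed digest
(HMAC-SHA256), standing in for asymmetric signatures. Consensus finality is
single-ledger (no forks); block timestamps are simulation-round indices.
"""

from __future__ import annotations

import hashlib
import hmac
import json
from dataclasses import dataclass, field

import numpy as np

from ledgerfed.errors import IdentityError, LedgerfedError

GENESIS_PREV_HASH = "0" * 64
BROADCAST = "*"

TX_KINDS = {
    "update_commitment",
    "reputation_state",
    "stake_state",
    "reward_event",
    "agreement_event",
    "audit_result",
}

_SCALAR_TYPES = (str, int, float, bool, type(None))


def hash_payload(data: bytes) -> str:
    """SHA-256 hex digest (m = 256 bits)."""
    return hashlib.sha256(data).hexdigest()


@dataclass(frozen=True)
class Transaction:
    sender: str
    receiver: str
    kind: str
    payload_digest: str
    payload_summary: dict
    round: int
    signature: str = ""

    def signing_body(self) -> bytes:
        body = dict(sender=self.sender, receiver=self.receiver, kind=self.kind,
                    payload_digest=self.payload_digest,
                    payload_summary=self.payload_summary, round=self.round)
        return json.dumps(body, sort_keys=True, separators=(",", ":")).encode()

    def as_dict(self) -> dict:
        return dict(sender=self.sender, receiver=self.receiver, kind=self.kind,
                    payload_digest=self.payload_digest,
                    payload_summary=self.payload_summary, round=self.round,
                    signature=self.signature)


@dataclass(frozen=True)
class Block:
    index: int
    prev_hash: str
    timestamp: int
    transactions: tuple[Transaction, ...]
    block_hash: str

    @staticmethod
    def compute_hash(index: int, prev_hash: str, timestamp: int,
                     transactions: tuple[Transaction, ...]) -> str:
        body = dict(index=index, prev_hash=prev_hash, timestamp=timestamp,
                    transactions=[t.as_dict() for t in transactions])
        return hash_payload(json.dumps(body, sort_keys=True, separators=(",", ":")).encode())


def _validate_summary(summary: dict) -> None:
    """Privacy boundary: summaries carry scalars only, never value arrays."""
    for k, v in summary.items():
        if not isinstance(k, str) or not isinstance(v, _SCALAR_TYPES):
            raise LedgerfedError(
                f"payload_summary entries must be scalar metadata, got {k}={type(v).__name__}"
            )


class Ledger:
    """Append-only block list plus node-key registry and off-chain store."""

    def __init__(self) -> None:
        self.blocks: list[Block] = []
        self._keys: dict[str, bytes] = {}
        self.artifacts: dict[str, bytes] = {}

    # -- identity -----------------------------------------------------------
    def register_node(self, node_id: str, seed: int = 0) -> None:
        key = hashlib.sha256(f"key:{node_id}:{seed}".encode()).digest()
        self._keys[node_id] = key

    def is_registered(self, node_id: str) -> bool:
        return node_id in self._keys

    def sign(self, tx: Transaction) -> Transaction:
        if tx.sender not in self._keys:
            raise IdentityError(f"unregistered sender: {tx.sender}")
        sig = hmac.new(self._keys[tx.sender], tx.signing_body(), hashlib.sha256).hexdigest()
        return Transaction(tx.sender, tx.receiver, tx.kind, tx.payload_digest,
                           tx.payload_summary, tx.round, sig)

    def verify_signature(self, tx: Transaction) -> bool:
        if tx.sender not in self._keys:
            return False
        expect = hmac.new(self._keys[tx.sender], tx.signing_body(), hashlib.sha256).hexdigest()
        return hmac.compare_digest(expect, tx.signature)

    def make_transaction(self, sender: str, kind: str, payload_digest: str,
                         payload_summary: dict, round_: int,
                         receiver: str = BROADCAST) -> Transaction:
        if kind not in TX_KINDS:
            raise LedgerfedError(f"unknown transaction kind: {kind}")
        _validate_summary(payload_summary)
        tx = Transaction(sender, receiver, kind, payload_digest, dict(payload_summary), round_)
        return self.sign(tx)

    # -- chain --------------------------------------------------------------
    def append_block(self, transactions: list[Transaction], timestamp: int | None = None) -> Block:
        """Append one block; the batch is rejected atomically if any
        signature fails, reporting the offending transaction index."""
        for i, tx in enumerate(transactions):
            if not self.verify_signature(tx):
                raise IdentityError(f"bad signature on transaction {i} (sender {tx.sender})")
        index = len(self.blocks)
        prev = self.blocks[-1].block_hash if self.blocks else GENESIS_PREV_HASH
        ts = index if timestamp is None else timestamp
        txs = tuple(transactions)
        block = Block(index, prev, ts, txs, Block.compute_hash(index, prev, ts, txs))
        self.blocks.append(block)
        return block

    def verify_chain(self) -> tuple[bool, int | None]:
        """Recompute every hash and link; returns (valid, first invalid index)."""
        prev = GENESIS_PREV_HASH
        for i, b in enumerate(self.blocks):
            if b.index != i or b.prev_hash != prev:
                return False, i
            if Block.compute_hash(b.index, b.prev_hash, b.timestamp, b.transactions) != b.block_hash:
                return False, i
            for tx in b.transactions:
                if not self.verify_signature(tx):
                    return False, i
            prev = b.block_hash
        return True, None

    # -- commitments --------------------------------------------------------
    def record_commitment(self, sender: str, artifact: bytes, kind: str, round_: int,
                          summary: dict | None = None, append: bool = True) -> Transaction:
        """Store the artifact off-chain and commit its digest on-chain."""
        if sender not in self._keys:
            raise IdentityError(f"unregistered sender: {sender}")
        digest = hash_payload(artifact)
        self.artifacts[digest] = bytes(artifact)
        tx = self.make_transaction(sender, kind, digest,
                                   dict(summary or {}, size_bytes=len(artifact)), round_)
        if append:
            self.append_block([tx], timestamp=round_)
        return tx

    def resolve(self, digest: str) -> bytes:
        if digest not in self.artifacts:
            raise LedgerfedError(f"no off-chain artifact for digest {digest[:12]}…")
        return self.artifacts[digest]

    # -- analytics ----------------------------------------------------------
    def all_transactions(self) -> list[Transaction]:
        return [tx for b in self.blocks for tx in b.transactions]

    def analytics(self) -> dict:
        """Pure function of the on-chain records: per-node commitment counts,
        audit outcomes, cumulative rewards and reputation trajectories."""
        per_node: dict[str, dict] = {}

        def node(nid: str) -> dict:
            return per_node.setdefault(nid, dict(
                commitments=0, audits_passed=0, audits_failed=0,
                total_reward=0.0, reputation_trajectory=[],
            ))

        for tx in self.all_transactions():
            if tx.kind == "update_commitment":
                node(tx.sender)["commitments"] += 1
            elif tx.kind == "audit_result":
                target = tx.payload_summary.get("node_id", tx.receiver)
                if tx.payload_summary.get("audit_pass"):
                    node(target)["audits_passed"] += 1
                else:
                    node(target)["audits_failed"] += 1
            elif tx.kind == "reward_event":
                target = tx.payload_summary.get("node_id", tx.receiver)
                node(target)["total_reward"] += float(tx.payload_summary.get("applied_amount", 0.0))
            elif tx.kind == "reputation_state":
                target = tx.payload_summary.get("node_id", tx.sender)
                node(target)["reputation_trajectory"].append(
                    (tx.round, float(tx.payload_summary.get("reputation", np.nan)))
                )
        total_rewards = sum(n["total_reward"] for n in per_node.values())
        return dict(per_node=per_node, total_rewards=total_rewards,
                    n_blocks=len(self.blocks),
                    n_transactions=len(self.all_transactions()))

    # -- export / import ----------------------------------------------------
    def export_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for b in self.blocks:
                fh.write(json.dumps(dict(
                    index=b.index, prev_hash=b.prev_hash, timestamp=b.timestamp,
                    block_hash=b.block_hash,
                    transactions=[t.as_dict() for t in b.transactions],
                ), sort_keys=True) + "\n")

    def import_jsonl(self, path) -> None:
        self.blocks = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                txs = tuple(Transaction(**t) for t in rec["transactions"])
                self.blocks.append(Block(rec["index"], rec["prev_hash"],
                                         rec["timestamp"], txs, rec["block_hash"]))


def tamper_block(ledger: Ledger, block_index: int, field_name: str = "timestamp") -> None:
    """Test helper: mutate one stored field in place (bypassing append-only
    discipline) so tamper evidence can be exercised."""
    b = ledger.blocks[block_index]
    if field_name == "timestamp":
        new = Block(b.index, b.prev_hash, b.timestamp + 1, b.transactions, b.block_hash)
    elif field_name == "prev_hash":
        new = Block(b.index, "f" * 64, b.timestamp, b.transactions, b.block_hash)
    elif field_name == "transaction" and b.transactions:
        tx = b.transactions[0]
        flipped = ("1" if tx.payload_digest[0] != "1" else "2") + tx.payload_digest[1:]
        mutated = Transaction(tx.sender, tx.receiver, tx.kind, flipped,
                              tx.payload_summary, tx.round, tx.signature)
        new = Block(b.index, b.prev_hash, b.timestamp,
                    (mutated,) + b.transactions[1:], b.block_hash)
    else:
        raise LedgerfedError(f"unknown tamper field {field_name}")
    ledger.blocks[block_index] = new
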