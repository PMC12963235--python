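"""Governance arithmetic: stake-proportional selection, committee sampling,
EMA stake with cap, reputation dynamics, contribution scoring and the token
reward rule — each against independent hand-coded oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ledgerfed import governance as gov
from ledgerfed import risk_model as rm
from ledgerfed.errors import DegenerateStakeError, SamplingError, ScoringError
from tests.test_risk_model import make_episodes


def node(nid, stake=1.0, rep=1.0, role="trainer"):
    return gov.NodeState(nid, role=role, stake=stake, reputation=rep)


class TestSelectionProbabilities:
    def test_proportional(self):
        probs = gov.selection_probabilities([node("A", 2), node("B", 1), node("C", 1)])
        assert probs == {"A": 0.5, "B": 0.25, "C": 0.25}

    def test_single_node_and_scale_invariance(self):
        assert gov.selection_probabilities([node("A", 3)]) == {"A": 1.0}
        nodes = [node("A", 0.3), node("B", 1.2), node("C", 0.5)]
        scaled = [node(n.node_id, n.stake * 10) for n in nodes]
        a = gov.selection_probabilities(nodes)
        b = gov.selection_probabilities(scaled)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_sum_to_one_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            nodes = [node(f"n{i}", float(rng.random() + 1e-6)) for i in range(int(rng.integers(1, 12)))]
            assert abs(sum(gov.selection_probabilities(nodes).values()) - 1.0) < 1e-12

    def test_degenerate_stakes(self):
        with pytest.raises(DegenerateStakeError):
            gov.selection_probabilities([node("A", 0.0), node("B", 0.0)])


class TestSampleCommittee:
    def test_committee_of_all_nodes(self):
        nodes = [node("A", 1), node("B", 2), node("C", 3)]
        cfg = gov.GovernanceConfig(committee_size=3)
        assert sorted(gov.sample_committee(nodes, cfg, 1, seed=0)) == ["A", "B", "C"]

    def test_rotation_excludes_previous(self):
        nodes = [node("A", 5), node("B", 1), node("C", 1)]
        cfg = gov.GovernanceConfig(committee_size=1, rotation_period=1)
        for seed in range(20):
            picked = gov.sample_committee(nodes, cfg, 2, seed=seed, previous_committee=["A"])
            assert picked[0] != "A"

    def test_first_draw_frequency_follows_stakes(self):
        nodes = [node("A", 3), node("B", 1)]
        cfg = gov.GovernanceConfig(committee_size=1)
        n = 20_000
        hits = sum(gov.sample_committee(nodes, cfg, 1, seed=s)[0] == "A" for s in range(n))
        tol = 3 * np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < tol

    def test_insufficient_nodes(self):
        with pytest.raises(SamplingError):
            gov.sample_committee([node("A")], gov.GovernanceConfig(committee_size=2), 0, 0)


class TestStake:
    def test_ema_arithmetic(self):
        cfg = gov.GovernanceConfig(ema_beta=0.9, stake_weights=(1.0, 0.0, 0.0))
        out = gov.update_stake(node("A", stake=1.0), 2.0, 1.0, cfg)
        assert out.stake == pytest.approx(1.1, abs=1e-12)

    def test_cap(self):
        cfg = gov.GovernanceConfig(ema_beta=0.9, stake_cap=1.05, stake_weights=(1.0, 0.0, 0.0))
        out = gov.update_stake(node("A", stake=1.0), 2.0, 1.0, cfg)
        assert out.stake == 1.05

    def test_fixed_point(self):
        cfg = gov.GovernanceConfig(ema_beta=0.8, stake_weights=(1.0, 0.0, 0.0))
        out = gov.update_stake(node("A", stake=0.5), 0.5, 1.0, cfg)
        assert out.stake == pytest.approx(0.5, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 5), st.floats(0, 1)), min_size=1, max_size=40),
           st.floats(0.2, 3.0))
    def test_cap_never_exceeded(self, updates, cap):
        """Anti-dominance: stake stays within the cap over any sequence."""
        cfg = gov.GovernanceConfig(stake_cap=cap)
        n = node("A", stake=min(1.0, cap))
        for utility, compliance in updates:
            n = gov.update_stake(n, utility, compliance, cfg, max_reputation=2.0)
            assert 0.0 <= n.stake <= cap + 1e-12


class TestReputation:
    def test_gain(self):
        cfg = gov.GovernanceConfig(reputation_decay=0.0, reputation_gain=1.0)
        assert gov.update_reputation(node("A", rep=1.0), 0.02, cfg).reputation == pytest.approx(1.02)

    def test_floor(self):
        cfg = gov.GovernanceConfig(reputation_floor=0.05)
        assert gov.update_reputation(node("A", rep=1.0), -100.0, cfg).reputation == 0.05

    def test_pure_decay(self):
        cfg = gov.GovernanceConfig(reputation_decay=0.1, reputation_gain=1.0)
        assert gov.update_reputation(node("A", rep=1.0), 0.0, cfg).reputation == pytest.approx(0.9)


@pytest.fixture(scope="module")
def setup():
    cfg = rm.test_preset(input_dim=8)
    params = rm.init_model(cfg, 0)
    val = make_episodes(40, 4, seed=9, separable=True)
    return cfg, params, val


class TestScoreContribution:
    def test_zero_update_zero_score(self, setup):
        cfg, params, val = setup
        zero = params - params
        sc = gov.score_contribution(params, zero, [1.0], val, cfg,
                                    gov.GovernanceConfig(), "n0", 0)
        assert sc.raw_delta_auroc == 0.0 and sc.c == 0.0 and sc.audit_pass

    def test_oversized_update_discounted_and_fails_audit(self, setup):
        cfg, params, val = setup
        update = rm.init_model(cfg, 1).scale(10.0)
        peer_norms = [update.norm() / 10.0] * 2  # median peer norm 10x smaller
        g = gov.GovernanceConfig(anomaly_discount=0.5)
        sc = gov.score_contribution(params, update, peer_norms, val, cfg, g, "n0", 0)
        assert sc.discount == 0.5 and not sc.audit_pass
        assert sc.c == sc.raw_delta_auroc * 0.5

    def test_c_equals_raw_when_no_anomaly(self, setup):
        cfg, params, val = setup
        update = rm.init_model(cfg, 2).scale(0.01)
        sc = gov.score_contribution(params, update, [update.norm()] * 2, val, cfg,
                                    gov.GovernanceConfig(), "n0", 0)
        assert sc.discount == 1.0 and sc.c == sc.raw_delta_auroc

    def test_single_class_validation_rejected(self, setup):
        cfg, params, _ = setup
        val = [e for e in make_episodes(10, 4, seed=10) if e.y == 0][:4]
        with pytest.raises(ScoringError):
            gov.score_contribution(params, params - params, [1.0], val, cfg,
                                   gov.GovernanceConfig(), "n0", 0)


class TestReward:
    @pytest.mark.parametrize("c,audit_pass,expected", [
        (0.3, True, 0.3),
        (-0.2, True, 0.0),
        (0.3, False, -0.2),
    ])
    def test_rule_examples(self, c, audit_pass, expected):
        cfg = gov.GovernanceConfig(lam=1.0, mu=0.5)
        assert gov.compute_reward(c, audit_pass, cfg) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_oracle_randomized(self):
        rng = np.random.default_rng(5)
        for _ in range(2000):
            lam = float(rng.uniform(0, 3))
            mu = float(rng.uniform(0, 2))
            c = float(rng.normal(0, 0.5))
            fail = bool(rng.integers(2))
            cap = float(rng.uniform(0.5, 5))
            cfg = gov.GovernanceConfig(lam=lam, mu=mu, reward_cap=cap)
            oracle = lam * max(0.0, c) - (mu if fail else 0.0)
            oracle = max(-cap, min(cap, oracle))
            assert gov.compute_reward(c, not fail, cfg) == oracle

    def test_balance_floor(self):
        n = gov.NodeState("A", tokens=1.0)
        n2, applied, shortfall = gov.apply_reward(n, -2.5)
        assert n2.tokens == 0.0 and applied == -1.0 and shortfall == 1.5
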