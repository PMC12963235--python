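"""Model correctness: analytic gradients against finite differences, the
parameter/FLOP count oracle, determinism contracts, and learning sanity."""

import numpy as np
import pytest

from ledgerfed import preprocess as prep
from ledgerfed import risk_model as rm
from ledgerfed.errors import ConfigurationError, ShapeError

TINY = rm.ModelConfig(input_dim=6, embed_dim=8, n_layers=2, n_heads=2,
                      ff_dim=12, dropout=0.0, clf_hidden=5, seq_len=4)


def make_episodes(n, d, seed=0, separable=False):
    """Synthetic normalized episodes; if separable, class means differ by 4 sd."""
    rng = np.random.default_rng(seed)
    eps = []
    for i in range(n):
        y = int(rng.random() < 0.5)
        shift = (4.0 if y else -4.0) if separable else 0.0
        X = rng.normal(shift * 0.25, 1.0, size=(48, d))
        M = (rng.random((48, d)) < 0.8).astype(np.int8)
        eps.append(prep.EpisodeTensor(f"p{i}", "s", X, M, y, True))
    return eps


def test_gradients_match_finite_differences():
    params = rm.init_model(TINY, seed=3)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(3, 4, 6))
    y = np.array([1.0, 0.0, 1.0])
    _, grads = rm.loss_and_grads(params, TINY, X, y, train=False)
    eps = 1e-6
    for name, arr in params.tensors.items():
        flat = arr.reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = rm.loss_and_grads(params, TINY, X, y, train=False)
            flat[i] = orig - eps
            lm, _ = rm.loss_and_grads(params, TINY, X, y, train=False)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name].reshape(-1)[i] == pytest.approx(num, abs=1e-7, rel=1e-5), name


class TestInit:
    def test_seed_determinism(self):
        assert rm.init_model(TINY, 5).digest() == rm.init_model(TINY, 5).digest()
        assert rm.init_model(TINY, 5).digest() != rm.init_model(TINY, 6).digest()

    def test_heads_divisibility(self):
        with pytest.raises(ConfigurationError):
            rm.ModelConfig(input_dim=4, embed_dim=10, n_heads=3)

    def test_param_count_analytic_oracle(self):
        """Independent per-layer hand computation of the test preset."""
        cfg = rm.test_preset(input_dim=32)  # E=32, L=1, H=2, F=64, clf 32
        E, F, H, Din = 32, 64, 32, 32
        embed = Din * E + E
        attn = 4 * (E * E + E)
        lns = 4 * E
        ffn = (E * F + F) + (F * E + E)
        clf = (E * H + H) + (H + 1)
        expected = embed + attn + lns + ffn + clf
        count, _ = rm.count_params_flops(cfg)
        assert count == expected
        actual = sum(v.size for v in rm.init_model(cfg, 0).tensors.values())
        assert actual == expected

    def test_flops_hand_computation(self):
        """FLOPs of the tiny config derived independently: 2 FLOPs per MAC
        over embedding, QKV, scores, weighting, output proj, FFN, classifier."""
        T, Din, E, F, H, L = 4, 6, 8, 12, 5, 2
        embed = 2 * T * Din * E
        attn = 6 * T * E * E + 2 * T * T * E + 2 * T * T * E + 2 * T * E * E
        ffn = 4 * T * E * F
        clf = 2 * (E * H + H)
        _, flops = rm.count_params_flops(TINY)
        assert flops == embed + L * (attn + ffn) + clf

    def test_counts_increase_with_depth(self):
        import dataclasses
        deeper = dataclasses.replace(TINY, n_layers=4)
        p1, f1 = rm.count_params_flops(TINY)
        p2, f2 = rm.count_params_flops(deeper)
        assert p2 > p1 and f2 > f1


class TestForward:
    def test_probability_range_and_equivariance(self):
        cfg = rm.test_preset(input_dim=8)
        params = rm.init_model(cfg, 1)
        eps = make_episodes(6, 4, seed=2)
        probs = rm.forward(params, cfg, eps)
        assert np.all((probs > 0) & (probs < 1))
        perm = [3, 1, 5, 0, 4, 2]
        probs_perm = rm.forward(params, cfg, [eps[i] for i in perm])
        np.testing.assert_array_equal(probs_perm, probs[perm])

    def test_eval_determinism_bitwise(self):
        cfg = rm.test_preset(input_dim=8)
        params = rm.init_model(cfg, 1)
        eps = make_episodes(4, 4, seed=2)
        np.testing.assert_array_equal(rm.forward(params, cfg, eps),
                                      rm.forward(params, cfg, eps))

    def test_shape_mismatch(self):
        cfg = rm.test_preset(input_dim=8)
        with pytest.raises(ShapeError):
            rm.forward(rm.init_model(cfg, 0), cfg, np.zeros((2, 48, 5)))


class TestTrainLocal:
    def test_zero_epochs_zero_update(self):
        cfg = rm.test_preset(input_dim=8)
        params = rm.init_model(cfg, 0)
        new, update = rm.train_local(params, make_episodes(8, 4), cfg,
                                     rm.TrainConfig(seed=0), epochs=0)
        assert update.norm() == 0.0
        assert new.digest() == params.digest()

    def test_update_additivity_and_determinism(self):
        cfg = rm.test_preset(input_dim=8)
        params = rm.init_model(cfg, 0)
        eps = make_episodes(16, 4, seed=1)
        tc = rm.TrainConfig(seed=7)
        new1, up1 = rm.train_local(params, eps, cfg, tc, epochs=1)
        new2, up2 = rm.train_local(params, eps, cfg, tc, epochs=1)
        assert new1.digest() == new2.digest()
        assert up1.digest() == up2.digest()
        assert (params + up1).digest() == new1.digest()

    def test_loss_decreases_on_separable_data(self):
        cfg = rm.test_preset(input_dim=8)
        params = rm.init_model(cfg, 0)
        eps = make_episodes(64, 4, seed=3, separable=True)
        X, y = rm.episodes_to_arrays(eps)
        before, _ = rm.loss_and_grads(params, cfg, X, y, train=False)
        new, _ = rm.train_local(params, eps, cfg, rm.TrainConfig(seed=0, lr=3e-3), epochs=1)
        after, _ = rm.loss_and_grads(new, cfg, X, y, train=False)
        assert after < before


class TestSchedule:
    def test_warmup_ramp(self):
        tc = rm.TrainConfig(lr=5e-4, max_epochs=20, patience=5)
        assert rm.lr_at_epoch(tc, 0) == pytest.approx(5e-4 / 5)
        assert rm.lr_at_epoch(tc, 4) == pytest.approx(5e-4)
        assert rm.lr_at_epoch(tc, 5) == pytest.approx(5e-4)  # cos(0)=1
        assert rm.lr_at_epoch(tc, 19) < rm.lr_at_epoch(tc, 10) < rm.lr_at_epoch(tc, 5)

    def test_history_and_best_checkpoint(self):
        cfg = rm.test_preset(input_dim=8)
        from ledgerfed.evaluation import auroc
        train = make_episodes(48, 4, seed=4, separable=True)
        val = make_episodes(24, 4, seed=5, separable=True)
        tc = rm.TrainConfig(seed=1, max_epochs=6, patience=3, lr=3e-3)
        best, hist = rm.train_centralized(train, val, cfg, tc)
        assert len(hist) <= tc.max_epochs
        Xv, yv = rm.episodes_to_arrays(val)
        best_val = auroc(yv, rm.forward(best, cfg, Xv))
        assert best_val == pytest.approx(max(h["val_auroc"] for h in hist), abs=1e-12)

    def test_empty_val_rejected(self):
        cfg = rm.test_preset(input_dim=8)
        with pytest.raises(ConfigurationError):
            rm.train_centralized(make_episodes(8, 4), [], cfg, rm.TrainConfig())


def test_learning_sanity_separable_cohort():
    """Test preset reaches validation AUROC >= 0.95 within 20 epochs on a
    linearly separable synthetic cohort."""
    from ledgerfed.evaluation import auroc
    cfg = rm.test_preset(input_dim=12)
    train = make_episodes(300, 6, seed=6, separable=True)
    val = make_episodes(100, 6, seed=7, separable=True)
    tc = rm.TrainConfig(seed=2, max_epochs=20, patience=19)
    best, hist = rm.train_centralized(train, val, cfg, tc)
    assert max(h["val_auroc"] for h in hist) >= 0.95


def test_aggregation_compatibility():
    """Linear combinations of parameter sets stay shape-valid and runnable."""
    cfg = rm.test_preset(input_dim=8)
    a, b = rm.init_model(cfg, 1), rm.init_model(cfg, 2)
    for w in (0.0, 0.3, 1.0):
        mix = rm.ModelParams.combine([a, b], [w, 1 - w])
        assert mix.same_schema(a)
        probs = rm.forward(mix, cfg, make_episodes(3, 4, seed=8))
        assert np.all((probs > 0) & (probs < 1))
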