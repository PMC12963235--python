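"""Pipeline correctness: gridding, winsor bounds, fill/mask/impute fixtures,
augmentation statistics, splits, and the train-only statistics guarantee."""

import numpy as np
import pandas as pd
import pytest

from ledgerfed import cohort as ch
from ledgerfed import preprocess as prep
from ledgerfed.errors import ConfigurationError, DataError, FitError, SchemaError, SplitError


def make_gridded(columns, label=0, pid="p0"):
    """Build a GriddedEpisode from per-variable lists (None = unobserved)."""
    arr = np.array([[np.nan if v is None else v for v in col] for col in columns], dtype=float).T
    return prep.GriddedEpisode(pid, "s", arr, label)


def identity_state(n_vars):
    return prep.PreprocessorState(
        variable_ids=[f"v{i}" for i in range(n_vars)],
        winsor_low=np.full(n_vars, -1e9), winsor_high=np.full(n_vars, 1e9),
        train_mean=np.zeros(n_vars), train_sd=np.ones(n_vars),
        impute_value=np.full(n_vars, 2.0))


class TestFilterEligible:
    def test_counts(self, tiny_variables):
        site = ch.single_site(3, n_variables=3)
        c = ch.generate_cohort(tiny_variables, [site], seed=1)
        c.outcomes.loc[0, "label"] = np.nan
        kept, excl = prep.filter_eligible(c)
        assert len(kept.outcomes) == 2
        assert excl == {"missing_label": 1, "insufficient_window": 0}

    def test_no_events_excluded(self, tiny_variables):
        site = ch.single_site(3, n_variables=3)
        c = ch.generate_cohort(tiny_variables, [site], seed=1)
        pid = c.outcomes["patient_id"].iloc[0]
        c.measurements = c.measurements[c.measurements["patient_id"] != pid].reset_index(drop=True)
        kept, excl = prep.filter_eligible(c)
        assert pid not in set(kept.outcomes["patient_id"])
        assert excl["insufficient_window"] == 1


class TestHourlyAggregate:
    def _cohort(self, rows):
        m = pd.DataFrame(rows, columns=ch.MEASUREMENTS_COLUMNS)
        o = pd.DataFrame({"patient_id": ["p0"], "label": [1]})
        return ch.RawCohort(m, pd.DataFrame(columns=ch.STATICS_COLUMNS), o,
                            pd.DataFrame(columns=ch.LATENT_COLUMNS), 48 * 60)

    def test_hour_mean_and_dedup_and_undefined(self):
        rows = [("p0", "s", "v0", 3 * 60 + 5, 4.0),
                ("p0", "s", "v0", 3 * 60 + 40, 6.0),
                ("p0", "s", "v0", 2 * 60, 9.0),
                ("p0", "s", "v0", 2 * 60, 9.0)]  # exact duplicate
        eps = prep.hourly_aggregate(self._cohort(rows), ["v0"])
        grid = eps[0].grid
        assert grid[3, 0] == 5.0
        assert grid[2, 0] == 9.0
        assert np.isnan(grid[7, 0])

    def test_negative_minutes_rejected(self):
        c = self._cohort([("p0", "s", "v0", -1, 4.0)])
        with pytest.raises(DataError):
            prep.hourly_aggregate(c, ["v0"])


class TestFit:
    def test_winsor_percentile_oracle(self):
        # spread the values 1..100 over several T=48 episodes
        vals = list(range(1, 101))
        eps = []
        for start in range(0, 100, 48):
            chunk = vals[start:start + 48]
            col = [float(v) for v in chunk] + [None] * (48 - len(chunk))
            eps.append(make_gridded([col], pid=f"p{start}"))
        state = prep.fit_preprocessor(eps, ["v0"])
        # linear-interpolation percentiles of {1..100}
        assert state.winsor_low[0] == pytest.approx(1.99, abs=1e-12)
        assert state.winsor_high[0] == pytest.approx(99.01, abs=1e-12)

    def test_constant_variable_maps_to_zero(self):
        eps = [make_gridded([[5.0] * 48])]
        state = prep.fit_preprocessor(eps, ["v0"])
        assert state.train_mean[0] == 5.0 and state.train_sd[0] == 0.0
        out = prep.transform(state, eps)[0]
        assert np.allclose(out.X, 0.0)

    def test_unobserved_variable_raises(self):
        eps = [make_gridded([[1.0] * 48, [None] * 48])]
        with pytest.raises(FitError, match="v1"):
            prep.fit_preprocessor(eps, ["v0", "v1"])

    def test_transform_deterministic(self, small_episodes):
        state = small_episodes["state"]
        eps = small_episodes["gridded"][:5]
        a = prep.transform(state, eps)
        b = prep.transform(state, eps)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.X, y.X)
            np.testing.assert_array_equal(x.M, y.M)


class TestTransform:
    def test_forward_fill_and_mask(self):
        ep = make_gridded([[None, 3.0, None, 5.0] + [None] * 44])
        out = prep.transform(identity_state(1), [ep])[0]
        np.testing.assert_array_equal(out.X[:4, 0], [2.0, 3.0, 3.0, 5.0])
        np.testing.assert_array_equal(out.M[:4, 0], [0, 1, 0, 1])
        # trailing cells carry the last observation forward
        assert np.all(out.X[4:, 0] == 5.0) and np.all(out.M[4:, 0] == 0)

    def test_winsor_clipping_before_normalization(self):
        state = identity_state(1)
        state.winsor_high = np.array([99.01])
        ep = make_gridded([[1000.0] + [None] * 47])
        out = prep.transform(state, [ep])[0]
        assert out.X[0, 0] == 99.01

    def test_fully_unobserved_column(self):
        ep = make_gridded([[1.0] * 48, [None] * 48])
        state = identity_state(2)
        out = prep.transform(state, [ep])[0]
        assert np.all(out.X[:, 1] == 2.0) and np.all(out.M[:, 1] == 0)

    def test_mask_matches_observations(self, small_episodes):
        for g, t in zip(small_episodes["gridded"][:10],
                        prep.transform(small_episodes["state"], small_episodes["gridded"][:10])):
            np.testing.assert_array_equal(t.M, (~np.isnan(g.grid)).astype(np.int8))
            assert not np.isnan(t.X).any()

    def test_schema_mismatch(self):
        ep = make_gridded([[1.0] * 48])
        with pytest.raises(SchemaError):
            prep.transform(identity_state(2), [ep])


class TestAugment:
    def _episodes(self, n, d):
        return [prep.EpisodeTensor(f"p{i}", "s", np.zeros((1, d)),
                                   np.ones((1, d), dtype=np.int8), 0, True)
                for i in range(n)]

    def test_identity(self, small_episodes):
        eps = small_episodes["tensors"][:5]
        out = prep.augment(eps, 0.0, 0.0, seed=1)
        for a, b in zip(eps, out):
            np.testing.assert_array_equal(a.X, b.X)
            np.testing.assert_array_equal(a.M, b.M)

    def test_mask_prob_one_zeroes_everything(self):
        out = prep.augment(self._episodes(3, 4), 0.0, 1.0, seed=1)
        for e in out:
            assert np.all(e.M == 0) and np.all(e.X == 0.0)

    def test_channel_mask_binomial(self):
        n, d = 5000, 20  # 1e5 independent channel draws
        out = prep.augment(self._episodes(n, d), 0.0, 0.2, seed=3)
        dropped = sum(int((e.M == 0).all(axis=0).sum()) for e in out)
        total = n * d
        tol = 3 * np.sqrt(total * 0.2 * 0.8)
        assert abs(dropped - 0.2 * total) < tol

    def test_bad_mask_prob(self):
        with pytest.raises(ConfigurationError):
            prep.augment([], 0.0, 1.5)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(10, (7, 1, 2)), (100, (70, 10, 20))])
    def test_sizes(self, n, expected):
        split = prep.split_cohort([f"p{i}" for i in range(n)], seed=0)
        sizes = tuple(len(split.patients(s)) for s in ("train", "val", "test"))
        assert sizes == expected

    def test_deterministic_and_disjoint(self):
        ids = [f"p{i}" for i in range(37)]
        a = prep.split_cohort(ids, seed=4)
        b = prep.split_cohort(ids, seed=4)
        assert a.assignment == b.assignment
        assert sorted(a.assignment) == sorted(ids)

    def test_too_few_patients(self):
        with pytest.raises(SplitError):
            prep.split_cohort(["a", "b"])


class TestNoLeakage:
    def test_sentinel_poisoning_leaves_state_unchanged(self, small_episodes):
        import copy

        vids = small_episodes["vids"]
        split = small_episodes["split"]
        # deep copy: the poisoning below must not leak into the shared fixture
        by_id = {k: copy.deepcopy(v) for k, v in small_episodes["by_id"].items()}
        train = [by_id[p] for p in sorted(split.patients("train"))]
        state1 = prep.fit_preprocessor(train, vids)
        # poison every non-train episode with a huge sentinel
        for p in sorted(split.patients("val")) + sorted(split.patients("test")):
            by_id[p].grid[:] = 1e12
        state2 = prep.fit_preprocessor(train, vids)
        np.testing.assert_array_equal(state1.winsor_low, state2.winsor_low)
        np.testing.assert_array_equal(state1.winsor_high, state2.winsor_high)
        np.testing.assert_array_equal(state1.train_mean, state2.train_mean)
        np.testing.assert_array_equal(state1.train_sd, state2.train_sd)
        # fitting on the poisoned sets yields visibly different statistics
        val = [by_id[p] for p in sorted(split.patients("val"))]
        state3 = prep.fit_preprocessor(val, vids)
        assert not np.allclose(state1.train_mean, state3.train_mean)
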