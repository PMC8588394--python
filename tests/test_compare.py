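"""Ranking and bootstrap comparison procedures: dominance behavior,
symmetry, p-value ordering, invariances and determinism."""

import numpy as np
import pytest

from glybench.compare import (
    LossMatrix,
    mcs,
    multi_horizon,
    pl_ranking,
    spa,
    stationary_bootstrap_indices,
)
from glybench.errors import AlignmentError


def lm(arr, ids=None, **kw):
    arr = np.asarray(arr, float)
    ids = ids or tuple(f"m{i}" for i in range(arr.shape[1]))
    return LossMatrix(arr, ids, **kw)


@pytest.fixture
def dominant(rng):
    base = rng.gamma(5.0, 4.0, size=(50, 1))
    return lm(
        np.hstack([base, base + rng.uniform(2, 5, (50, 1)), base + rng.uniform(2, 5, (50, 1))]),
        ("A", "B", "C"),
    )


class TestLossMatrix:
    def test_validation(self, rng):
        with pytest.raises(ValueError):
            lm(rng.gamma(2, 1, (10, 1)))  # single model
        with pytest.raises(ValueError):
            lm(-np.ones((10, 3)))
        bad = rng.gamma(2, 1, (10, 3))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            lm(bad)

    def test_multi_horizon_concatenation(self, rng):
        a = lm(rng.gamma(2, 1, (60, 3)), ("x", "y", "z"), horizon="30")
        b = lm(rng.gamma(2, 1, (60, 3)), ("x", "y", "z"), horizon="60")
        combo = multi_horizon(a, b)
        assert combo.losses.shape == (120, 3)
        assert combo.horizon == "30∪60"
        np.testing.assert_allclose(
            combo.losses.mean(axis=0), (a.losses.mean(axis=0) + b.losses.mean(axis=0)) / 2
        )

    def test_multi_horizon_model_mismatch(self, rng):
        a = lm(rng.gamma(2, 1, (20, 2)), ("x", "y"))
        b = lm(rng.gamma(2, 1, (20, 2)), ("x", "w"))
        with pytest.raises(AlignmentError):
            multi_horizon(a, b)


class TestPlackettLuce:
    def test_dominant_model_wins(self, dominant):
        res = pl_ranking(dominant, seed=1)
        probs = res.as_dict()
        assert probs["A"] > 0.9
        assert probs["A"] > probs["B"] and probs["A"] > probs["C"]

    def test_probabilities_sum_to_one(self, dominant):
        res = pl_ranking(dominant, seed=2)
        assert res.p_best.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.ci_low <= res.p_best) and np.all(res.p_best <= res.ci_high)

    def test_exchangeable_losses_symmetric(self, rng):
        res = pl_ranking(lm(rng.gamma(5, 4, size=(200, 4))), seed=3)
        np.testing.assert_allclose(res.p_best, 0.25, atol=0.06)

    def test_all_tied_rows_dropped_with_warning(self, rng):
        losses = rng.gamma(5, 4, size=(30, 3))
        losses[:5] = 7.0  # five uninformative rows
        with pytest.warns(UserWarning):
            res = pl_ranking(lm(losses), seed=4)
        assert res.p_best.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_only_scale_invariant(self, dominant):
        res_a = pl_ranking(dominant, seed=5)
        res_b = pl_ranking(
            LossMatrix(dominant.losses * 37.0, dominant.model_ids), seed=5
        )
        np.testing.assert_array_equal(res_a.p_best, res_b.p_best)

    def test_seeded_reproducibility(self, dominant):
        a = pl_ranking(dominant, seed=6)
        b = pl_ranking(dominant, seed=6)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestMCS:
    def test_strictly_dominated_model_eliminated(self, rng):
        base = rng.gamma(5, 4, size=(40, 1))
        res = mcs(lm(np.hstack([base, base + 10.0]), ("good", "bad")), seed=1)
        assert res.survivors == ("good",)
        assert res.p_values["good"] == 1.0
        assert res.p_values["bad"] <= 0.05

    def test_survivor_set_never_empty(self, rng):
        for trial in range(10):
            losses = np.random.default_rng(trial).gamma(2, 3, size=(30, 4))
            res = mcs(lm(losses), n_bootstrap=200, seed=trial)
            assert len(res.survivors) >= 1

    def test_duplicate_model_handled(self, rng):
        base = rng.gamma(5, 4, size=(40, 1))
        dup = np.hstack([base, base, base + 8.0])
        res = mcs(lm(dup, ("a", "a_copy", "worse")), seed=2)
        assert "a" in res.survivors and "a_copy" in res.survivors

    def test_fully_tied_set_all_survive(self):
        res = mcs(lm(np.full((20, 3), 5.0)), seed=3)
        assert len(res.survivors) == 3

    def test_scale_invariance_bitwise(self, rng):
        losses = rng.gamma(5, 4, size=(40, 4))
        a = mcs(lm(losses), n_bootstrap=300, seed=4)
        b = mcs(lm(losses * 11.0), n_bootstrap=300, seed=4)
        assert a.survivors == b.survivors
        assert a.p_values == b.p_values

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            mcs(lm(rng.gamma(2, 1, (5, 3))))


class TestSPA:
    def test_dominant_benchmark_high_consistent_p(self, rng):
        base = rng.gamma(5, 4, size=(40, 1))
        res = spa(lm(np.hstack([base, base + 10.0]), ("bench", "rival")), "bench", seed=1)
        assert res.p_consistent > 0.9

    def test_dominated_benchmark_low_consistent_p(self, rng):
        base = rng.gamma(5, 4, size=(40, 1))
        res = spa(lm(np.hstack([base + 10.0, base]), ("bench", "rival")), "bench", seed=1)
        assert res.p_consistent < 0.05

    def test_p_value_ordering_on_random_matrices(self):
        for trial in range(40):
            losses = np.random.default_rng(300 + trial).gamma(5, 4, size=(40, 4))
            res = spa(lm(losses), "m0", n_bootstrap=300, seed=trial)
            assert res.p_lower <= res.p_consistent <= res.p_upper

    def test_unknown_benchmark_rejected(self, rng):
        with pytest.raises(KeyError):
            spa(lm(rng.gamma(2, 1, (20, 3))), "nope")

    def test_seeded_reproducibility(self, rng):
        losses = rng.gamma(5, 4, size=(40, 3))
        a = spa(lm(losses), "m1", seed=9)
        b = spa(lm(losses), "m1", seed=9)
        assert a.as_tuple() == b.as_tuple()


def test_stationary_bootstrap_indices_shape_and_range(rng):
    idx = stationary_bootstrap_indices(37, 100, 5.0, rng)
    assert idx.shape == (100, 37)
    assert idx.min() >= 0 and idx.max() < 37
    # consecutive indices within a block wrap modulo n
    diffs = np.diff(idx, axis=1) % 37
    assert set(np.unique(diffs)).issubset(set(range(37)))
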