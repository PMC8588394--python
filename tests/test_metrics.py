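"""Metric suite: closed-form limits, hand-checked values, oracle
equivalence and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glybench.errors import UndefinedMetricError
from glybench.metrics import METRIC_NAMES, aggregate_patients, compute_metrics
from glybench.zoo import PredictionSet


def naive_oracle(actual, predicted):
    """Independent loop-based evaluation of the seven metrics."""
    n = len(actual)
    mse = sum((p - a) ** 2 for a, p in zip(actual, predicted)) / n
    mae = sum(abs(p - a) for a, p in zip(actual, predicted)) / n
    mard = sum(abs(p - a) / a for a, p in zip(actual, predicted)) / n
    abar = sum(actual) / n
    pbar = sum(predicted) / n
    sstot = sum((a - abar) ** 2 for a in actual)
    r2 = 1 - sum((p - a) ** 2 for a, p in zip(actual, predicted)) / sstot
    num = sum((p - pbar) * (a - abar) for a, p in zip(actual, predicted))
    den = (
        sum((p - pbar) ** 2 for p in predicted) * sum((a - abar) ** 2 for a in actual)
    ) ** 0.5
    cc = num / den
    fit = 1 - sum(abs(p - a) for a, p in zip(actual, predicted)) / sum(
        abs(a - abar) for a in actual
    )
    return {
        "mse": mse,
        "rmse": mse**0.5,
        "mae": mae,
        "r2": r2,
        "cc": cc,
        "fit": fit,
        "mard": mard,
    }


def ps(actual, predicted, pid="p1", model="m", horizon=30):
    return PredictionSet(pid, horizon, np.asarray(actual, float), np.asarray(predicted, float), model)


class TestClosedForms:
    def test_perfect_prediction(self):
        y = np.array([80.0, 120.0, 200.0, 90.0])
        row = compute_metrics(ps(y, y))
        assert row["mse"] == row["rmse"] == row["mae"] == row["mard"] == 0.0
        assert row["r2"] == row["cc"] == row["fit"] == 1.0

    def test_mean_predictor_zeroes_r2_and_fit(self):
        y = np.array([80.0, 120.0, 200.0, 90.0])
        row = compute_metrics(ps(y, np.full_like(y, y.mean())))
        assert row["r2"] == pytest.approx(0.0, abs=1e-12)
        assert row["fit"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_checked_example(self):
        row = compute_metrics(ps([100.0, 200.0], [110.0, 180.0]))
        assert row["mae"] == pytest.approx(15.0)
        assert row["mard"] == pytest.approx(0.10)
        assert row["mse"] == pytest.approx(250.0)
        assert row["rmse"] == pytest.approx(np.sqrt(250.0))

    def test_rmse_is_sqrt_mse_and_ranges(self, rng):
        y = rng.uniform(60, 300, 50)
        p = np.clip(y + rng.normal(0, 20, 50), 40, 400)
        row = compute_metrics(ps(y, p))
        assert row["rmse"] == pytest.approx(np.sqrt(row["mse"]), abs=1e-12)
        assert -1 <= row["cc"] <= 1 and row["r2"] <= 1 and row["mard"] >= 0


def test_equivalence_with_loop_oracle(rng):
    """Vectorized metrics match the naive loop oracle to 1e-10."""
    worst = 0.0
    for _ in range(1000):
        n = rng.integers(2, 40)
        y = rng.uniform(41, 399, n)
        p = np.clip(y + rng.normal(0, 30, n), 40, 400)
        if np.ptp(y) == 0 or np.ptp(p) == 0:
            continue
        row = compute_metrics(ps(y, p))
        want = naive_oracle(y.tolist(), p.tolist())
        worst = max(worst, max(abs(row[k] - want[k]) for k in METRIC_NAMES))
    assert worst < 1e-10


class TestInvariances:
    @given(a=st.floats(0.5, 3.0), b=st.floats(-20.0, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_cc_affine_invariant(self, a, b):
        rng = np.random.default_rng(5)
        y = rng.uniform(60, 300, 30)
        p = y + rng.normal(0, 15, 30)
        base = compute_metrics(ps(y, p))["cc"]
        moved = compute_metrics(ps(y, a * p + b))["cc"]
        assert moved == pytest.approx(base, abs=1e-9)

    def test_mard_scale_invariant(self, rng):
        y = rng.uniform(60, 300, 30)
        p = y + rng.normal(0, 15, 30)
        assert compute_metrics(ps(2 * y, 2 * p))["mard"] == pytest.approx(
            compute_metrics(ps(y, p))["mard"], abs=1e-12
        )


class TestDegenerate:
    def test_single_point_strict_raises(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ps([100.0], [105.0]), strict=True)

    def test_single_point_lenient_nans_only_unexplainable(self):
        row = compute_metrics(ps([100.0], [105.0]))
        assert row["mae"] == 5.0
        assert np.isnan(row["r2"]) and np.isnan(row["cc"]) and np.isnan(row["fit"])

    def test_zero_variance_strict_raises(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ps([100.0, 100.0], [90.0, 95.0]), strict=True)

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ps([0.0, 100.0], [50.0, 50.0]))


class TestAggregation:
    def rows(self, rmses, model="m", horizon=30):
        out = []
        for i, r in enumerate(rmses):
            out.append(
                {
                    "model_id": model,
                    "patient_id": f"p{i}",
                    "horizon": horizon,
                    "n": 10,
                    **{m: r for m in METRIC_NAMES},
                }
            )
        return out

    def test_identical_rows_sem_zero(self):
        table = aggregate_patients(self.rows([20.0, 20.0, 20.0]))
        assert table.loc[0, "rmse_sem"] == 0.0

    def test_two_patient_closed_form(self):
        table = aggregate_patients(self.rows([18.0, 22.0]))
        assert table.loc[0, "rmse_mean"] == pytest.approx(20.0)
        assert table.loc[0, "rmse_sem"] == pytest.approx(2.0)

    def test_permutation_invariant(self):
        a = aggregate_patients(self.rows([18.0, 25.0, 31.0]))
        b = aggregate_patients(self.rows([31.0, 18.0, 25.0]))
        assert a.loc[0, "rmse_mean"] == b.loc[0, "rmse_mean"]
        assert a.loc[0, "rmse_sem"] == b.loc[0, "rmse_sem"]

    def test_single_patient_sem_absent(self):
        table = aggregate_patients(self.rows([20.0]))
        assert np.isnan(table.loc[0, "rmse_sem"])
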