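"""Seven-metric evaluation suite with per-patient aggregation.

For n aligned pairs (y_t actual, yhat_t predicted, mg/dL):

    MSE  = (1/n) sum (yhat - y)^2
    RMSE = sqrt(MSE)
    MAE  = (1/n) sum |yhat - y|
    R2   = 1 - sum (yhat - y)^2 / sum (y - ybar)^2
    CC   = Pearson correlation of yhat and y
    Fit  = 1 - sum |yhat - y| / sum |y - ybar|
    MARD = (1/n) sum |yhat - y| / y

Fit is the absolute-residual analogue of R2: zero for the mean predictor,
one for perfect prediction, negative when predictions are farther from
the targets than the constant mean forecast. Reports aggregate across
patients as mean +/- standard error of the mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .zoo import PredictionSet

__all__ = ["METRIC_NAMES", "compute_metrics", "aggregate_patients"]

METRIC_NAMES = ("mse", "rmse", "mae", "r2", "cc", "fit", "mard")


def compute_metrics(pred: PredictionSet, strict: bool = False) -> dict:
    """One row of the metric suite for a prediction set.

    R2, CC and Fit are undefined for n < 2 or zero actual variance; with
    ``strict`` they raise, otherwise they are NaN while the error metrics
    are still computed.
    """
    y = pred.actual
    yhat = pred.predicted
    n = len(y)
    if n == 0:
        raise ValueError("empty prediction set")
    if np.any(y <= 0):
        raise ValueError("actual glucose must be positive (MARD denominator)")
    err = yhat - y
    row = {
        "model_id": pred.model_id,
        "patient_id": pred.patient_id,
        "horizon": pred.horizon,
        "n": n,
        "mse": float(np.mean(err**2)),
        "mae": float(np.mean(np.abs(err))),
        "mard": float(np.mean(np.abs(err) / y)),
    }
    row["rmse"] = float(np.sqrt(row["mse"]))
    ybar = y.mean()
    sstot = float(np.sum((y - ybar) ** 2))
    degenerate = n < 2 or sstot == 0.0
    if degenerate:
        if strict:
            raise UndefinedMetricError(
                "R2/CC/Fit undefined: n < 2 or zero actual variance"
            )
        row.update({"r2": np.nan, "cc": np.nan, "fit": np.nan})
        return row
    row["r2"] = float(1.0 - np.sum(err**2) / sstot)
    sd_hat = float(np.sqrt(np.sum((yhat - yhat.mean()) ** 2)))
    if sd_hat == 0.0:
        row["cc"] = np.nan if not strict else None
        if strict:
            raise UndefinedMetricError("CC undefined: constant predictions")
    else:
        row["cc"] = float(
            np.sum((yhat - yhat.mean()) * (y - ybar))
            / (sd_hat * np.sqrt(np.sum((y - ybar) ** 2)))
        )
    row["fit"] = float(1.0 - np.sum(np.abs(err)) / np.sum(np.abs(y - ybar)))
    return row


def aggregate_patients(rows) -> pd.DataFrame:
    """Mean +/- SEM of each metric across patients.

    Input rows are :func:`compute_metrics` dicts (one per patient) for one
    (model, horizon) cell; multiple models/horizons may be mixed and are
    grouped. SEM uses the sample standard deviation over k patients
    divided by sqrt(k), and is NaN for a single patient.
    """
    df = pd.DataFrame(list(rows))
    out = []
    for (model, horizon), g in df.groupby(["model_id", "horizon"], sort=True):
        rec = {"model_id": model, "horizon": horizon, "n_patients": len(g)}
        for m in METRIC_NAMES:
            vals = g[m].to_numpy(dtype=float)
            rec[f"{m}_mean"] = float(np.nanmean(vals))
            if len(g) >= 2:
                rec[f"{m}_sem"] = float(np.nanstd(vals, ddof=1) / np.sqrt(len(g)))
            else:
                rec[f"{m}_sem"] = np.nan
        out.append(rec)
    return pd.DataFrame(out)
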