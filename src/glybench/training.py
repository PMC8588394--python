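"""Uniform training and cross-validation protocol for every zoo model.

All architectures train under identical conditions — Adam at learning rate
0.01, 100 epochs with early stopping at 10 epochs' patience monitoring
validation loss, mean absolute error as the companion metric — differing
only in the loss their head requires (MSE, Gaussian negative
log-likelihood, or risk-bin cross-entropy). Validation uses repeated
contiguous 80/20 splits of the training windows with a shifting origin
(ten repetitions), which preserves temporal order; the chronological test
partition is predicted once per fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .errors import GlybenchError
from .nn import Adam, Tensor, gaussian_nll_loss, mse_loss, softmax_cross_entropy
from .series import (
    PatientSeries,
    WindowedDataset,
    clip_predictions,
    compute_scaling_stats,
    fill_gaps,
    make_windows,
    scale_features,
    unscale_bg,
)
from .zoo import (
    ENSEMBLE_MEMBERS,
    Network,
    PredictionSet,
    StackedModel,
    build_model,
    ensemble_predict,
    risk_encode,
)

__all__ = [
    "TrainingProtocol",
    "TrainingFailure",
    "train_model",
    "fit_stacked",
    "cross_validate",
    "fold_split",
    "last_value_baseline",
    "preprocess_series",
]


class TrainingFailure(GlybenchError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class TrainingProtocol:
    """The common training conditions applied to every architecture."""

    learning_rate: float = 0.01
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    folds: int = 10
    train_fraction_per_fold: float = 0.8
    classic_kfold: bool = False  # contiguous 1/folds validation blocks instead
    seed: int = 0


def _targets_for(net: Network, dataset: WindowedDataset, horizon: int):
    y_scaled = dataset.targets[horizon]
    if net.loss == "categorical":
        return risk_encode(unscale_bg(y_scaled))
    return y_scaled.reshape(-1, 1)


def _batch_loss(net: Network, xb, yb) -> Tensor:
    out = net.forward(xb, training=True)
    if net.loss == "mse":
        return mse_loss(out, yb)
    if net.loss == "gaussian_nll":
        mu, sigma = out
        return gaussian_nll_loss(yb, mu, sigma)
    return softmax_cross_entropy(out, yb)


def _eval_loss(net: Network, x, y, batch_size: int = 512) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        out = net.forward(xb, training=False)
        if net.loss == "mse":
            val = float(np.mean((out.data - yb) ** 2))
        elif net.loss == "gaussian_nll":
            mu, sigma = out
            val = float(
                np.mean(
                    0.5 * np.log(2 * np.pi * sigma.data**2)
                    + (yb - mu.data) ** 2 / (2 * sigma.data**2)
                )
            )
        else:
            z = out.data - out.data.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            val = float(-logp[np.arange(len(yb)), np.asarray(yb, int)].mean())
        total += val * len(xb)
        n += len(xb)
    return total / max(n, 1)


def train_model(
    spec_id_or_net,
    train_data: WindowedDataset,
    val_data: WindowedDataset,
    horizon: int,
    protocol: TrainingProtocol = TrainingProtocol(),
):
    """Fit one architecture under the common protocol.

    Returns ``(model, history)`` where history holds per-epoch train and
    validation loss and mean absolute error (mg/dL). Early stopping
    restores the best-validation-epoch weights. The stacked-generalization
    spec dispatches to :func:`fit_stacked`.
    """
    if isinstance(spec_id_or_net, str):
        if spec_id_or_net == "khadem":
            model = build_model("khadem", seed=protocol.seed)
            return fit_stacked(model, train_data, val_data, horizon, protocol)
        if spec_id_or_net in ENSEMBLE_MEMBERS:
            raise ValueError(
                "ensembles are evaluated from trained members; train the members"
            )
        net = build_model(spec_id_or_net, seed=protocol.seed)
    else:
        net = spec_id_or_net
    if isinstance(net, StackedModel):
        return fit_stacked(net, train_data, val_data, horizon, protocol)

    x_train = train_data.inputs
    y_train = _targets_for(net, train_data, horizon)
    x_val = val_data.inputs
    y_val = _targets_for(net, val_data, horizon)
    if len(x_train) == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 1]))
    opt = Adam(net.params, learning_rate=protocol.learning_rate)
    history = {"loss": [], "val_loss": [], "mae": [], "val_mae": []}
    best_val = math.inf
    best_weights = net.get_weights()
    wait = 0
    actual_train = unscale_bg(train_data.targets[horizon])
    actual_val = unscale_bg(val_data.targets[horizon])

    for epoch in range(protocol.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), protocol.batch_size):
            idx = order[i : i + protocol.batch_size]
            loss = _batch_loss(net, x_train[idx], y_train[idx])
            if not np.isfinite(loss.data):
                raise TrainingFailure(f"{net.spec_id}: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        val_loss = _eval_loss(net, x_val, y_val) if len(x_val) else math.nan
        history["loss"].append(epoch_loss / seen)
        history["val_loss"].append(val_loss)
        history["mae"].append(
            float(np.mean(np.abs(net.predict(x_train) - actual_train)))
        )
        history["val_mae"].append(
            float(np.mean(np.abs(net.predict(x_val) - actual_val)))
            if len(x_val)
            else math.nan
        )
        if len(x_val) and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
            if len(x_val) and wait >= protocol.patience:
                break
    if len(x_val):
        net.set_weights(best_weights)
    return net, history


def fit_stacked(
    model: StackedModel,
    train_data: WindowedDataset,
    val_data: WindowedDataset,
    horizon: int,
    protocol: TrainingProtocol,
):
    """Fit the stacked-generalization model (NN/PLSR bases + PLSR meta)."""
    for h in model.BASE_HORIZONS:
        if h not in train_data.targets:
            raise ValueError(
                f"stacked model needs {model.BASE_HORIZONS} min targets in the windows"
            )
    histories = {}
    for (kind, h), net in model.nn_bases.items():
        _, histories[f"{kind}_{h}"] = train_model(net, train_data, val_data, h, protocol)
    flat = train_data.inputs.reshape(len(train_data.inputs), -1)
    for h in model.BASE_HORIZONS:
        pls = PLSRegression(n_components=5, scale=True)
        pls.fit(flat, train_data.targets[h])
        model.plsr_bases[h] = pls
    base = model.base_outputs(train_data.inputs)
    meta = PLSRegression(n_components=min(4, base.shape[1]), scale=True)
    meta.fit(base, train_data.targets[horizon])
    model.meta = meta
    return model, histories


def fold_split(n_windows: int, fold: int, protocol: TrainingProtocol):
    """Contiguous train/validation split for one fold, temporal order kept.

    Default: an 80/20 split whose validation block starts at
    ``fold * n / folds`` and wraps, so the blocks cover every window
    across folds. With ``classic_kfold`` the validation block is the
    fold-th contiguous 1/folds slice (disjoint blocks, 90/10 at ten
    folds).
    """
    if protocol.classic_kfold:
        start = int(round(fold * n_windows / protocol.folds))
        stop = int(round((fold + 1) * n_windows / protocol.folds))
        val_idx = np.arange(start, max(stop, start + 1))
    else:
        n_val = max(1, int(round((1.0 - protocol.train_fraction_per_fold) * n_windows)))
        start = int(round(fold * n_windows / protocol.folds)) % n_windows
        val_idx = (start + np.arange(n_val)) % n_windows
    mask = np.ones(n_windows, dtype=bool)
    mask[val_idx] = False
    return np.flatnonzero(mask), val_idx


def _subset(data: WindowedDataset, idx: np.ndarray) -> WindowedDataset:
    return WindowedDataset(
        inputs=data.inputs[idx],
        targets={h: t[idx] for h, t in data.targets.items()},
        horizons=data.horizons,
    )


def preprocess_series(series: PatientSeries, horizons) -> tuple:
    """fill gaps -> fit scaling on train -> scale -> window both partitions."""
    filled = fill_gaps(series)
    stats = compute_scaling_stats(filled)
    scaled = scale_features(filled, stats)
    train_w = make_windows(scaled, horizons=horizons, partition="train")
    test_w = make_windows(scaled, horizons=horizons, partition="test")
    return train_w, test_w


def last_value_baseline(windows: WindowedDataset, horizon: int) -> PredictionSet:
    """Naive persistence forecast: carry the window's last glucose forward."""
    predicted = clip_predictions(unscale_bg(windows.inputs[:, -1, 0]), "naive")
    actual = unscale_bg(windows.targets[horizon])
    return PredictionSet("", horizon, actual, predicted, "naive_last_value")


def cross_validate(
    spec_id: str,
    series_list,
    horizon: int,
    protocol: TrainingProtocol = TrainingProtocol(),
    horizons=None,
):
    """Run the repeated-split protocol for one spec over a cohort.

    Returns a dict with per-(fold, patient) test-partition
    :class:`PredictionSet` objects and the matching RMSE matrix
    (rows = fold x patient evaluation units) that feeds the ranking and
    bootstrap comparison procedures.
    """
    if horizons is None:
        horizons = (30, 60, 120) if spec_id != "khadem" else (30, 60, horizon)
        horizons = tuple(sorted(set(horizons) | {horizon}))
    predictions = []
    rmse_rows = []
    members = ENSEMBLE_MEMBERS.get(spec_id)
    for series in series_list:
        train_w, test_w = preprocess_series(series, horizons)
        actual = unscale_bg(test_w.targets[horizon])
        for fold in range(protocol.folds):
            tr_idx, va_idx = fold_split(len(train_w), fold, protocol)
            proto_f = dc_replace(protocol, seed=protocol.seed + fold)
            if members:
                preds = []
                for m in members:
                    net, _ = train_model(
                        m, _subset(train_w, tr_idx), _subset(train_w, va_idx), horizon, proto_f
                    )
                    preds.append(net.predict(test_w.inputs))
                predicted = ensemble_predict(preds)
            else:
                model, _ = train_model(
                    spec_id, _subset(train_w, tr_idx), _subset(train_w, va_idx), horizon, proto_f
                )
                predicted = model.predict(test_w.inputs)
            ps = PredictionSet(series.patient_id, horizon, actual, predicted, spec_id)
            predictions.append((fold, ps))
            rmse_rows.append(
                {
                    "fold": fold,
                    "patient_id": series.patient_id,
                    "rmse": float(np.sqrt(np.mean((predicted - actual) ** 2))),
                }
            )
    return {"predictions": predictions, "rmse": rmse_rows}
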