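"""Catalog and builders for the glucose-forecasting model zoo.

Ten published architectures plus two averaging ensembles, every one
consuming the same (batch, 25, 4) scaled window:

======================  =====================================================
spec id                 architecture sketch
======================  =====================================================
``mirshekarian``        LSTM(5) -> dense(1)
``meijner``             LSTM(4) -> parallel dense mean / dense ELU scale,
                        trained by Gaussian negative log-likelihood
``gulesir``             two conv(4 filters, width 5) + max-pool stages ->
                        dense(1)
``sun``                 LSTM(4, sequences) -> bidirectional LSTM(4, concat)
                        -> dense 4/64/4 -> dense(1)
``idriss``              LSTM(50) -> dense 30/30 -> dense(1)
``aiello``              two 2xLSTM(64) branches: full 25x4 window and the
                        last 30 min of the three non-glucose channels
``zhu``                 three vanilla-RNN(32) layers, dilation 1/2/4
``mayo``                LSTM(12, sequences) -> flatten -> batchnorm ->
                        dense(50, relu) -> batchnorm -> 100 risk-bin logits
``munoz``               per-channel LSTM(10)->dense(3) branches with a
                        carb/insulin intermediate unit
``khadem``              stacked generalization: six base learners (dense,
                        LSTM, PLSR at 30- and 60-min targets) under a PLSR
                        meta-learner
``ensemble_mms``        arithmetic mean of mirshekarian, meijner, sun
``ensemble_mmsz``       arithmetic mean of mirshekarian, meijner, sun, zhu
======================  =====================================================

Parameter totals of the built graphs reproduce the published counts
exactly for the first eight entries (206, 154, 181, 1053, 13491, 101249,
5377, 22366).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .nn import (
    BatchNorm,
    Bidirectional,
    Conv1D,
    Dense,
    Flatten,
    LSTM,
    MaxPool1D,
    SimpleRNN,
    Tensor,
    concat,
)
from .series import BG_MAX, BG_MIN, clip_predictions, unscale_bg

__all__ = [
    "SPEC_IDS",
    "BASE_SPEC_IDS",
    "ENSEMBLE_MEMBERS",
    "PRINTED_PARAM_COUNTS",
    "PredictionSet",
    "Network",
    "StackedModel",
    "EnsembleModel",
    "build_model",
    "count_parameters",
    "gaussian_nll",
    "risk_encode",
    "risk_decode",
    "risk_transform",
    "N_RISK_BINS",
    "ensemble_predict",
]

BASE_SPEC_IDS = (
    "mirshekarian",
    "meijner",
    "gulesir",
    "sun",
    "idriss",
    "aiello",
    "zhu",
    "mayo",
    "munoz",
    "khadem",
)
ENSEMBLE_MEMBERS = {
    "ensemble_mms": ("mirshekarian", "meijner", "sun"),
    "ensemble_mmsz": ("mirshekarian", "meijner", "sun", "zhu"),
}
SPEC_IDS = BASE_SPEC_IDS + tuple(ENSEMBLE_MEMBERS)

#: published totals that the built graphs must reproduce exactly
PRINTED_PARAM_COUNTS = {
    "mirshekarian": 206,
    "meijner": 154,
    "gulesir": 181,
    "sun": 1053,
    "idriss": 13491,
    "aiello": 101249,
    "zhu": 5377,
    "mayo": 22366,
}


@dataclass
class PredictionSet:
    """Aligned (actual, predicted) mg/dL pairs for one model/patient/horizon."""

    patient_id: str
    horizon: int
    actual: np.ndarray
    predicted: np.ndarray
    model_id: str

    def __post_init__(self):
        self.actual = np.asarray(self.actual, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.actual.shape != self.predicted.shape:
            raise AlignmentError(
                f"{self.model_id}: {len(self.actual)} actual vs "
                f"{len(self.predicted)} predicted"
            )

    def __len__(self) -> int:
        return len(self.actual)


# --------------------------------------------------------------- risk domain
# Monotone logarithmic symmetrization of the glucose scale,
# f(bg) = gamma * ((ln bg)^alpha - beta), with the classic curvature
# exponent alpha and (beta, gamma) calibrated so f(40) = -2 and
# f(400) = +2. Hypo- and hyperglycemia then span equal widths.
RISK_ALPHA = 1.084
_A40 = np.log(40.0) ** RISK_ALPHA
_A400 = np.log(400.0) ** RISK_ALPHA
RISK_GAMMA = 4.0 / (_A400 - _A40)
RISK_BETA = 0.5 * (_A40 + _A400)
N_RISK_BINS = 100
_BIN_WIDTH = 4.0 / N_RISK_BINS


def risk_transform(bg) -> np.ndarray:
    """Map glucose in [40, 400] mg/dL onto the symmetric risk scale [-2, 2]."""
    bg = np.asarray(bg, dtype=float)
    if np.any(bg < BG_MIN) or np.any(bg > BG_MAX):
        raise ValueError(f"bg outside [{BG_MIN}, {BG_MAX}] mg/dL")
    return RISK_GAMMA * (np.log(bg) ** RISK_ALPHA - RISK_BETA)


def risk_encode(bg) -> np.ndarray:
    """Glucose -> index of its risk-scale bin (0..99)."""
    r = risk_transform(bg)
    bins = np.floor((r + 2.0) / _BIN_WIDTH).astype(int)
    return np.clip(bins, 0, N_RISK_BINS - 1)


def risk_decode(bins) -> np.ndarray:
    """Bin index -> glucose (mg/dL) of the bin center."""
    bins = np.asarray(bins, dtype=int)
    if np.any(bins < 0) or np.any(bins >= N_RISK_BINS):
        raise ValueError("bin index outside 0..99")
    r = -2.0 + (bins + 0.5) * _BIN_WIDTH
    return np.exp((r / RISK_GAMMA + RISK_BETA) ** (1.0 / RISK_ALPHA))


# --------------------------------------------------------------------- losses
def gaussian_nll(actual, mu, sigma) -> float:
    """Mean negative Gaussian log-density of ``actual`` under N(mu, sigma^2)."""
    actual, mu, sigma = (np.asarray(a, dtype=float) for a in (actual, mu, sigma))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return float(
        np.mean(
            0.5 * np.log(2.0 * np.pi * sigma**2) + (actual - mu) ** 2 / (2 * sigma**2)
        )
    )


# ------------------------------------------------------------------ networks
class Network:
    """A built architecture: layers plus a forward wiring function.

    ``forward`` maps an input Tensor (batch, 25, 4) to the raw head output;
    ``predict`` maps a plain array to clipped mg/dL predictions through the
    spec's output decoder.
    """

    def __init__(self, spec_id, layers, forward_fn, loss: str, decoder: str):
        self.spec_id = spec_id
        self.layers = layers
        self._forward = forward_fn
        self.loss = loss  # mse | gaussian_nll | categorical
        self.decoder = decoder  # identity | bin_to_bg

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def count_parameters(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def forward(self, x, training: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        return self._forward(x, training)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Clipped mg/dL predictions for a (n, 25, 4) array."""
        outs = []
        for i in range(0, len(x), batch_size):
            out = self.forward(x[i : i + batch_size], training=False)
            if self.loss == "gaussian_nll":
                out = out[0]  # mean head
            outs.append(out.data)
        raw = np.concatenate(outs, axis=0)
        if self.decoder == "bin_to_bg":
            mgdl = risk_decode(np.argmax(raw, axis=1))
        else:
            mgdl = unscale_bg(raw.ravel())
        return clip_predictions(mgdl, model_id=self.spec_id)

    def get_weights(self):
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p.data = w.copy()


class EnsembleModel:
    """Arithmetic-mean ensemble over independently trained member networks."""

    def __init__(self, spec_id: str, members: dict):
        self.spec_id = spec_id
        self.members = members  # spec_id -> Network

    def count_parameters(self) -> int:
        return sum(m.count_parameters() for m in self.members.values())

    def predict(self, x: np.ndarray) -> np.ndarray:
        return ensemble_predict([m.predict(x) for m in self.members.values()])


class StackedModel:
    """Stacked generalization: NN and PLSR base learners under a PLSR meta.

    Base learners are trained at fixed 30- and 60-minute targets; the
    partial-least-squares meta-learner maps their six outputs to the
    requested horizon. Fitting lives in :mod:`glybench.training`; parameter
    counting covers the neural base learners (PLSR coefficients excluded).
    """

    BASE_HORIZONS = (30, 60)

    def __init__(self, spec_id: str, nn_bases: dict, rng: np.random.Generator):
        self.spec_id = spec_id
        self.nn_bases = nn_bases  # (kind, horizon) -> Network
        self.plsr_bases = {}  # horizon -> fitted sklearn PLSRegression
        self.meta = None  # fitted PLSRegression over base outputs
        self.rng = rng

    def count_parameters(self) -> int:
        return sum(m.count_parameters() for m in self.nn_bases.values())

    def base_outputs(self, x: np.ndarray) -> np.ndarray:
        """(n, 6) matrix of scaled-bg base-learner predictions."""
        cols = []
        flat = x.reshape(len(x), -1)
        for h in self.BASE_HORIZONS:
            for kind in ("dense", "lstm"):
                net = self.nn_bases[(kind, h)]
                out = net.forward(x, training=False).data.ravel()
                cols.append(out)
            cols.append(self.plsr_bases[h].predict(flat).ravel())
        return np.stack(cols, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.meta is None:
            raise RuntimeError("StackedModel must be fitted before predicting")
        scaled = self.meta.predict(self.base_outputs(x)).ravel()
        return clip_predictions(unscale_bg(scaled), model_id=self.spec_id)


def ensemble_predict(member_predictions) -> np.ndarray:
    """Element-wise arithmetic mean of aligned member predictions, clipped."""
    if len(member_predictions) < 2:
        raise ValueError("an ensemble needs at least two members")
    arrays = [np.asarray(m, dtype=float) for m in member_predictions]
    n = {len(a) for a in arrays}
    if len(n) != 1:
        raise AlignmentError(f"member prediction lengths differ: {sorted(n)}")
    return clip_predictions(np.mean(arrays, axis=0), model_id="ensemble")


# ------------------------------------------------------------------ builders
def _build_mirshekarian(steps, feats, rng):
    lstm = LSTM(feats, 5, rng)
    out = Dense(5, 1, "linear", rng)
    return Network(
        "mirshekarian",
        [lstm, out],
        lambda x, tr: out(lstm(x, tr), tr),
        "mse",
        "identity",
    )


def _build_meijner(steps, feats, rng):
    lstm = LSTM(feats, 4, rng)
    mean_head = Dense(4, 1, "linear", rng)
    scale_head = Dense(4, 1, "linear", rng)

    def fwd(x, tr):
        h = lstm(x, tr)
        mu = mean_head(h, tr)
        # ELU(x)+1+eps keeps the scale head strictly positive
        sigma = scale_head(h, tr).elu() + (1.0 + 1e-6)
        return mu, sigma

    return Network("meijner", [lstm, mean_head, scale_head], fwd, "gaussian_nll", "identity")


def _build_gulesir(steps, feats, rng):
    conv1 = Conv1D(feats, 4, 5, "relu", rng)
    pool = MaxPool1D(2)
    conv2 = Conv1D(4, 4, 5, "relu", rng)
    flat = Flatten()
    # 25 -conv5-> 21 -pool-> 10 -conv5-> 6 -pool-> 3, times 4 filters
    out = Dense(12, 1, "linear", rng)

    def fwd(x, tr):
        h = pool(conv2(pool(conv1(x, tr), tr), tr), tr)
        return out(flat(h, tr), tr)

    return Network("gulesir", [conv1, conv2, out], fwd, "mse", "identity")


def _build_sun(steps, feats, rng):
    lstm = LSTM(feats, 4, rng, return_sequences=True)
    bi = Bidirectional(lambda go_backwards: LSTM(4, 4, rng, go_backwards=go_backwards))
    d1 = Dense(8, 4, "linear", rng)
    d2 = Dense(4, 64, "linear", rng)
    d3 = Dense(64, 4, "linear", rng)
    out = Dense(4, 1, "linear", rng)

    def fwd(x, tr):
        return out(d3(d2(d1(bi(lstm(x, tr), tr), tr), tr), tr), tr)

    return Network("sun", [lstm, bi, d1, d2, d3, out], fwd, "mse", "identity")


def _build_idriss(steps, feats, rng):
    lstm = LSTM(feats, 50, rng)
    d1 = Dense(50, 30, "linear", rng)
    d2 = Dense(30, 30, "linear", rng)
    out = Dense(30, 1, "linear", rng)

    def fwd(x, tr):
        return out(d2(d1(lstm(x, tr), tr), tr), tr)

    return Network("idriss", [lstm, d1, d2, out], fwd, "mse", "identity")


def _build_aiello(steps, feats, rng):
    # branch 1: the full 25-step, 4-channel window
    b1a = LSTM(feats, 64, rng, return_sequences=True)
    b1b = LSTM(64, 64, rng)
    # branch 2: the last 30 min (6 steps) of the 3 known-future channels
    b2a = LSTM(feats - 1, 64, rng, return_sequences=True)
    b2b = LSTM(64, 64, rng)
    out = Dense(128, 1, "linear", rng)

    def fwd(x, tr):
        h1 = b1b(b1a(x, tr), tr)
        h2 = b2b(b2a(x[:, -6:, 1:], tr), tr)
        return out(concat([h1, h2], axis=-1), tr)

    return Network("aiello", [b1a, b1b, b2a, b2b, out], fwd, "mse", "identity")


def _build_zhu(steps, feats, rng):
    r1 = SimpleRNN(feats, 32, rng, dilation=1, return_sequences=True)
    r2 = SimpleRNN(32, 32, rng, dilation=2, return_sequences=True)
    r3 = SimpleRNN(32, 32, rng, dilation=4)
    out = Dense(32, 1, "linear", rng)

    def fwd(x, tr):
        return out(r3(r2(r1(x, tr), tr), tr), tr)

    return Network("zhu", [r1, r2, r3, out], fwd, "mse", "identity")


def _build_mayo(steps, feats, rng):
    lstm = LSTM(feats, 12, rng, return_sequences=True)
    flat = Flatten()
    bn1 = BatchNorm(12 * steps)
    d1 = Dense(12 * steps, 50, "relu", rng)
    bn2 = BatchNorm(50)
    out = Dense(50, N_RISK_BINS, "linear", rng)

    def fwd(x, tr):
        return out(bn2(d1(bn1(flat(lstm(x, tr), tr), tr), tr), tr), tr)

    return Network("mayo", [lstm, bn1, d1, bn2, out], fwd, "categorical", "bin_to_bg")


def _build_munoz(steps, feats, rng):
    branches = []
    for _ in range(feats):
        branches.append(
            (
                LSTM(1, 10, rng, activation="relu"),
                Dense(10, 3, "relu", rng),
            )
        )
    inter = Dense(9, 1, "linear", rng)  # carb + insulin pathways merged
    out = Dense(4, 1, "linear", rng)

    def fwd(x, tr):
        feats_out = []
        for c, (lstm, dense) in enumerate(branches):
            feats_out.append(dense(lstm(x[:, :, c : c + 1], tr), tr))
        non_bg = inter(concat(feats_out[1:], axis=-1), tr)
        return out(concat([feats_out[0], non_bg], axis=-1), tr)

    layers = [l for pair in branches for l in pair] + [inter, out]
    return Network("munoz", layers, fwd, "mse", "identity")


def _build_khadem_base(kind: str, steps, feats, rng) -> Network:
    if kind == "dense":
        flat = Flatten()
        d1 = Dense(steps * feats, 100, "relu", rng)
        out = Dense(100, 1, "relu", rng)
        return Network(
            "khadem_dense",
            [d1, out],
            lambda x, tr: out(d1(flat(x, tr), tr), tr),
            "mse",
            "identity",
        )
    lstm = LSTM(feats, 200, rng, activation="relu")
    d1 = Dense(200, 100, "relu", rng)
    out = Dense(100, 1, "relu", rng)
    return Network(
        "khadem_lstm",
        [lstm, d1, out],
        lambda x, tr: out(d1(lstm(x, tr), tr), tr),
        "mse",
        "identity",
    )


_BUILDERS = {
    "mirshekarian": _build_mirshekarian,
    "meijner": _build_meijner,
    "gulesir": _build_gulesir,
    "sun": _build_sun,
    "idriss": _build_idriss,
    "aiello": _build_aiello,
    "zhu": _build_zhu,
    "mayo": _build_mayo,
    "munoz": _build_munoz,
}


def build_model(spec_id: str, input_steps: int = 25, n_features: int = 4, seed: int = 0):
    """Instantiate a zoo architecture with seeded initial weights."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, _spec_key(spec_id)]))
    if spec_id in _BUILDERS:
        return _BUILDERS[spec_id](input_steps, n_features, rng)
    if spec_id == "khadem":
        bases = {}
        for h in StackedModel.BASE_HORIZONS:
            for kind in ("dense", "lstm"):
                bases[(kind, h)] = _build_khadem_base(kind, input_steps, n_features, rng)
        return StackedModel("khadem", bases, rng)
    if spec_id in ENSEMBLE_MEMBERS:
        members = {
            m: build_model(m, input_steps, n_features, seed) for m in ENSEMBLE_MEMBERS[spec_id]
        }
        return EnsembleModel(spec_id, members)
    raise KeyError(f"unknown spec_id {spec_id!r}; known: {SPEC_IDS}")


def _spec_key(spec_id: str) -> int:
    return SPEC_IDS.index(spec_id) if spec_id in SPEC_IDS else 99


def count_parameters(model) -> int:
    """Total parameters (trainable + normalization statistics) of a model."""
    return model.count_parameters()


CATALOG_VERSION = 1


def catalog() -> dict:
    """Machine-readable catalog of the zoo (serializable to YAML/JSON)."""
    sketches = {
        "mirshekarian": "lstm(5) -> dense(1, linear)",
        "meijner": "lstm(4) -> [dense(1, linear) mean | dense(1, elu+1) scale]",
        "gulesir": "conv1d(4f, k5, relu) -> maxpool(2) -> conv1d(4f, k5, relu) "
        "-> maxpool(2) -> flatten -> dense(1, linear)",
        "sun": "lstm(4, seq) -> bilstm(4, concat) -> dense(4/64/4, linear) -> dense(1)",
        "idriss": "lstm(50) -> dense(30, linear) -> dense(30, linear) -> dense(1)",
        "aiello": "[2x lstm(64) on 25x4 | 2x lstm(64) on last 6x3] -> concat -> dense(1)",
        "zhu": "rnn(32, d=1, seq) -> rnn(32, d=2, seq) -> rnn(32, d=4) -> dense(1)",
        "mayo": "lstm(12, seq) -> flatten -> batchnorm -> dense(50, relu) "
        "-> batchnorm -> dense(100 risk-bin logits)",
        "munoz": "4x [lstm(10, relu) -> dense(3, relu)] per channel; "
        "non-bg branches -> dense(1) -> concat with bg branch -> dense(1)",
        "khadem": "stacked: {dense, lstm(200), plsr} bases at 30/60 min "
        "-> plsr meta-learner",
        "ensemble_mms": "mean(mirshekarian, meijner, sun)",
        "ensemble_mmsz": "mean(mirshekarian, meijner, sun, zhu)",
    }
    losses = {"meijner": "gaussian_nll", "mayo": "categorical"}
    entries = {}
    for spec in SPEC_IDS:
        entries[spec] = {
            "architecture": sketches[spec],
            "loss": losses.get(spec, "mse"),
            "members": list(ENSEMBLE_MEMBERS.get(spec, [])),
            "built_parameters": count_parameters(build_model(spec)),
            "published_parameters": PRINTED_PARAM_COUNTS.get(spec),
        }
    return {"catalog_version": CATALOG_VERSION, "input_shape": [25, 4], "models": entries}
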