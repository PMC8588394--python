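"""Trainable layers for the forecasting model zoo.

Shapes follow the channels-last convention: sequence inputs are
``(batch, steps, features)``. Parameter layouts and counts match the
standard Keras conventions (fused 4*units LSTM kernels in i,f,c,o order,
unpadded convolutions, floor-division pooling, batch-norm moving statistics
counted as parameters) so that architecture audits against published
parameter totals are exact.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, maximum, stack_last

__all__ = [
    "Dense",
    "LSTM",
    "Bidirectional",
    "SimpleRNN",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "BatchNorm",
    "ACTIVATIONS",
]

ACTIVATIONS = {
    "linear": lambda t: t,
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "relu": lambda t: t.relu(),
    "elu": lambda t: t.elu(),
}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Layer:
    """Base class: tracks trainable tensors and total parameter count."""

    def __init__(self):
        self.params: list[Tensor] = []
        self.extra_state_size = 0  # non-trainable numbers (e.g. BN moving stats)

    def param_count(self) -> int:
        return sum(p.data.size for p in self.params) + self.extra_state_size

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, units: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, n_in, units, (n_in, units))
        self.b = Tensor(np.zeros(units), requires_grad=True)
        self.act = ACTIVATIONS[activation]
        self.params = [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.act(x @ self.w + self.b)


class LSTM(Layer):
    """Standard gated recurrent layer (input/forget/cell/output gates).

    ``activation`` shapes the cell candidate and hidden output;
    ``recurrent_activation`` shapes the three gates.
    """

    def __init__(
        self,
        n_in: int,
        units: int,
        rng: np.random.Generator,
        activation: str = "tanh",
        recurrent_activation: str = "sigmoid",
        return_sequences: bool = False,
        go_backwards: bool = False,
    ):
        super().__init__()
        self.units = units
        self.wx = _glorot(rng, n_in, 4 * units, (n_in, 4 * units))
        self.wh = _glorot(rng, units, 4 * units, (units, 4 * units))
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # unit forget-gate bias eases early training
        self.b = Tensor(bias, requires_grad=True)
        self.act = ACTIVATIONS[activation]
        self.rec_act = ACTIVATIONS[recurrent_activation]
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.params = [self.wx, self.wh, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        batch, steps, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((batch, u)))
        c = Tensor(np.zeros((batch, u)))
        order = range(steps - 1, -1, -1) if self.go_backwards else range(steps)
        outputs = []
        for t in order:
            z = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = self.rec_act(z[:, 0:u])
            f = self.rec_act(z[:, u : 2 * u])
            g = self.act(z[:, 2 * u : 3 * u])
            o = self.rec_act(z[:, 3 * u : 4 * u])
            c = f * c + i * g
            h = o * self.act(c)
            outputs.append(h)
        if not self.return_sequences:
            return h
        if self.go_backwards:
            outputs = outputs[::-1]
        return stack_last(outputs)


class Bidirectional(Layer):
    """Runs a forward and a backward recurrent copy and merges by concat."""

    def __init__(self, make_layer):
        super().__init__()
        self.fwd = make_layer(go_backwards=False)
        self.bwd = make_layer(go_backwards=True)
        self.params = self.fwd.params + self.bwd.params

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return concat([self.fwd(x, training), self.bwd(x, training)], axis=-1)


class SimpleRNN(Layer):
    """Vanilla recurrent layer with optional dilation.

    With dilation rate d the hidden state feeding step t is the state from
    step t-d, so layer stacks with rates 1,2,4 see exponentially growing
    receptive fields at constant parameter cost.
    """

    def __init__(
        self,
        n_in: int,
        units: int,
        rng: np.random.Generator,
        activation: str = "tanh",
        dilation: int = 1,
        return_sequences: bool = False,
    ):
        super().__init__()
        self.units = units
        self.wx = _glorot(rng, n_in, units, (n_in, units))
        self.wh = _glorot(rng, units, units, (units, units))
        self.b = Tensor(np.zeros(units), requires_grad=True)
        self.act = ACTIVATIONS[activation]
        self.dilation = dilation
        self.return_sequences = return_sequences
        self.params = [self.wx, self.wh, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        batch, steps, _ = x.shape
        zero = Tensor(np.zeros((batch, self.units)))
        outputs: list[Tensor] = []
        for t in range(steps):
            h_prev = outputs[t - self.dilation] if t >= self.dilation else zero
            outputs.append(self.act(x[:, t, :] @ self.wx + h_prev @ self.wh + self.b))
        return stack_last(outputs) if self.return_sequences else outputs[-1]


class Conv1D(Layer):
    """Unpadded 1-D convolution over the time axis (channels last)."""

    def __init__(self, n_in: int, filters: int, kernel_size: int, activation: str, rng):
        super().__init__()
        self.kernel_size = kernel_size
        fan_in, fan_out = kernel_size * n_in, kernel_size * filters
        self.w = _glorot(rng, fan_in, fan_out, (kernel_size, n_in, filters))
        self.b = Tensor(np.zeros(filters), requires_grad=True)
        self.act = ACTIVATIONS[activation]
        self.params = [self.w, self.b]

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        steps = x.shape[1]
        l_out = steps - self.kernel_size + 1
        out = None
        for k in range(self.kernel_size):
            term = x[:, k : k + l_out, :] @ self.w[k]
            out = term if out is None else out + term
        return self.act(out + self.b)


class MaxPool1D(Layer):
    """Pooling with window = stride = ``pool_size`` and floor truncation."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        if pool_size != 2:
            raise NotImplementedError("only pool_size=2 is used by the zoo")

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        n = (x.shape[1] // 2) * 2
        return maximum(x[:, 0:n:2, :], x[:, 1:n:2, :])


class Flatten(Layer):
    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return x.reshape(x.shape[0], -1)


class BatchNorm(Layer):
    """Batch normalization over axis 0 of a 2-D activation.

    Trainable scale/shift plus moving mean/variance; the moving statistics
    are counted in ``param_count`` (they are part of the serialized model).
    """

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.moving_mean = np.zeros(n_features)
        self.moving_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.extra_state_size = 2 * n_features

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = (x - mu).square().mean(axis=0, keepdims=True)
            m = self.momentum
            self.moving_mean = m * self.moving_mean + (1 - m) * mu.data.ravel()
            self.moving_var = m * self.moving_var + (1 - m) * var.data.ravel()
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.moving_mean)) / Tensor(
                np.sqrt(self.moving_var + self.eps)
            )
        return xhat * self.gamma + self.beta
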