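"""Single-layer LSTM sequence classifier in NumPy.

The recurrence is the standard gated cell: input, forget and output gates are
sigmoids of affine maps of the current input and previous hidden state, the
candidate is a tanh, the memory cell is ``c_t = i_t * tanh(W_c x + U_c h + b_c)
+ f_t * c_{t-1}``, and the hidden state is ``h_t = o_t * tanh(c_t)``.  Class
logits come from a separate affine readout of the final hidden state, followed
by a softmax; the whole model is trained jointly on cross-entropy with Adam,
with the learning rate annealed as ``lr / (1 + decay * epoch)`` and the
returned parameters taken from the epoch with the best validation loss.

Weight matrices are stored (hidden x input) and (hidden x hidden); inputs may
be a single (t, d) sequence or a batch (b, t, d).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

GATE_NAMES = ("i", "f", "o", "c")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LSTMParams:
    """Gate weights (hidden x input / hidden x hidden), biases, and readout."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray
    W_out: np.ndarray  # classes x hidden
    b_out: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_i.shape
        if h < 1:
            raise ValueError("hidden size must be >= 1")
        for g in GATE_NAMES:
            if getattr(self, f"W_{g}").shape != (h, d):
                raise ValueError(f"W_{g} shape mismatch")
            if getattr(self, f"U_{g}").shape != (h, h):
                raise ValueError(f"U_{g} shape mismatch")
            if getattr(self, f"b_{g}").shape != (h,):
                raise ValueError(f"b_{g} shape mismatch")
        if self.W_out.shape[1] != h or self.b_out.shape != (self.W_out.shape[0],):
            raise ValueError("readout shape mismatch")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1]

    @property
    def n_classes(self) -> int:
        return self.W_out.shape[0]

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def copy(self) -> "LSTMParams":
        return LSTMParams(**{k: v.copy() for k, v in self.arrays().items()})


def init_params(
    rng: np.random.Generator,
    input_size: int,
    hidden_size: int,
    n_classes: int,
    forget_bias: float = 1.0,
) -> LSTMParams:
    """Glorot-uniform weights, zero biases except the forget gate's (+1)."""

    def glorot(n_out: int, n_in: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_out, n_in))

    kw = {}
    for g in GATE_NAMES:
        kw[f"W_{g}"] = glorot(hidden_size, input_size)
        kw[f"U_{g}"] = glorot(hidden_size, hidden_size)
        kw[f"b_{g}"] = np.zeros(hidden_size)
    kw["b_f"] = np.full(hidden_size, forget_bias, dtype=float)
    kw["W_out"] = glorot(n_classes, hidden_size)
    kw["b_out"] = np.zeros(n_classes)
    return LSTMParams(**kw)


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gated recurrence; inputs may be batched on axis 0."""
    for a in (x_t, h_prev, c_prev):
        if not np.isfinite(a).all():
            raise ValueError("non-finite input to lstm_step")
    i = sigmoid(x_t @ p.W_i.T + h_prev @ p.U_i.T + p.b_i)
    f = sigmoid(x_t @ p.W_f.T + h_prev @ p.U_f.T + p.b_f)
    o = sigmoid(x_t @ p.W_o.T + h_prev @ p.U_o.T + p.b_o)
    g = np.tanh(x_t @ p.W_c.T + h_prev @ p.U_c.T + p.b_c)
    c = i * g + f * c_prev
    h = o * np.tanh(c)
    return h, c


def lstm_forward(seq: np.ndarray, p: LSTMParams) -> np.ndarray:
    """Class probabilities after iterating the recurrence from h = c = 0.

    ``seq`` is (t, d) for one trial or (b, t, d) for a batch; the readout and
    softmax apply to the final hidden state.
    """
    seq = np.asarray(seq, dtype=np.float64)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    b, t, d = seq.shape
    if t < 1:
        raise ValueError("sequence must have at least one step")
    if d != p.input_size:
        raise ValueError(
            f"feature dimension {d} does not match trained input size {p.input_size}"
        )
    h = np.zeros((b, p.hidden_size))
    c = np.zeros((b, p.hidden_size))
    for step in range(t):
        h, c = lstm_step(seq[:, step], h, c, p)
    probs = softmax(h @ p.W_out.T + p.b_out)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# Training: cross-entropy, full backprop-through-time, Adam


def _forward_cached(X: np.ndarray, p: LSTMParams) -> dict:
    b, t, _ = X.shape
    H = p.hidden_size
    cache = {
        "i": np.empty((t, b, H)), "f": np.empty((t, b, H)),
        "o": np.empty((t, b, H)), "g": np.empty((t, b, H)),
        "c": np.empty((t + 1, b, H)), "h": np.empty((t + 1, b, H)),
    }
    cache["c"][0] = 0.0
    cache["h"][0] = 0.0
    for s in range(t):
        x = X[:, s]
        h_prev, c_prev = cache["h"][s], cache["c"][s]
        i = sigmoid(x @ p.W_i.T + h_prev @ p.U_i.T + p.b_i)
        f = sigmoid(x @ p.W_f.T + h_prev @ p.U_f.T + p.b_f)
        o = sigmoid(x @ p.W_o.T + h_prev @ p.U_o.T + p.b_o)
        g = np.tanh(x @ p.W_c.T + h_prev @ p.U_c.T + p.b_c)
        c = i * g + f * c_prev
        cache["i"][s], cache["f"][s], cache["o"][s], cache["g"][s] = i, f, o, g
        cache["c"][s + 1] = c
        cache["h"][s + 1] = o * np.tanh(c)
    logits = cache["h"][t] @ p.W_out.T + p.b_out
    cache["probs"] = softmax(logits)
    return cache


def _backward(X: np.ndarray, y_onehot: np.ndarray, p: LSTMParams, cache: dict) -> dict:
    """Gradients of the mean cross-entropy w.r.t. every parameter array."""
    b, t, _ = X.shape
    grads = {k: np.zeros_like(v) for k, v in p.arrays().items()}
    dlogits = (cache["probs"] - y_onehot) / b
    grads["W_out"] = dlogits.T @ cache["h"][t]
    grads["b_out"] = dlogits.sum(axis=0)
    dh = dlogits @ p.W_out
    dc = np.zeros((b, p.hidden_size))
    for s in range(t - 1, -1, -1):
        i, f, o, g = cache["i"][s], cache["f"][s], cache["o"][s], cache["g"][s]
        c, c_prev, h_prev = cache["c"][s + 1], cache["c"][s], cache["h"][s]
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = {
            "i": di * i * (1.0 - i),
            "f": df * f * (1.0 - f),
            "o": do * o * (1.0 - o),
            "c": dg * (1.0 - g**2),
        }
        x = X[:, s]
        dh = np.zeros_like(dh)
        for gate, dzg in dz.items():
            grads[f"W_{gate}"] += dzg.T @ x
            grads[f"U_{gate}"] += dzg.T @ h_prev
            grads[f"b_{gate}"] += dzg.sum(axis=0)
            dh += dzg @ getattr(p, f"U_{gate}")
        dc = dc * f
    return grads


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


@dataclass
class TrainConfig:
    """Optimizer and schedule settings for the sequence decoder."""

    hidden_size: int = 32
    learning_rate: float = 1e-3
    lr_decay_per_epoch: float = 5e-4
    max_epochs: int = 200
    batch_size: int = 16
    forget_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("rates, epochs and batch size must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def fit_lstm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_classes: int,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[LSTMParams, TrainHistory]:
    """Train with Adam on cross-entropy; return the best-validation snapshot.

    ``y`` are integer class indices in [0, n_classes).  The learning rate at
    epoch ``e`` (0-based) is ``lr / (1 + decay * e)``.  Divergence (non-finite
    loss) raises, reporting the epoch.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if len(X_val) == 0:
        raise ValueError("validation set must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    p = init_params(rng, X_train.shape[2], cfg.hidden_size, n_classes, cfg.forget_bias)
    onehot = np.eye(n_classes)[y_train]

    m = {k: np.zeros_like(v) for k, v in p.arrays().items()}
    v = {k: np.zeros_like(a) for k, a in p.arrays().items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best = p.copy()
    best_acc = -np.inf
    best_loss = np.inf
    hist = TrainHistory()
    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate / (1.0 + cfg.lr_decay_per_epoch * epoch)
        for idx in _minibatches(len(X_train), cfg.batch_size, rng):
            cache = _forward_cached(X_train[idx], p)
            grads = _backward(X_train[idx], onehot[idx], p, cache)
            step += 1
            for k, arr in p.arrays().items():
                gk = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk**2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                arr -= lr * mhat / (np.sqrt(vhat) + eps)
        train_probs = lstm_forward(X_train, p)
        val_probs = lstm_forward(X_val, p)
        tl = cross_entropy(train_probs, y_train)
        vl = cross_entropy(val_probs, y_val)
        if not np.isfinite(tl) or not np.isfinite(vl):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        hist.train_loss.append(tl)
        hist.val_loss.append(vl)
        va = float((val_probs.argmax(1) == y_val).mean())
        hist.val_accuracy.append(va)
        # best validation performance: accuracy first, loss as tie-break
        if va > best_acc or (va == best_acc and vl < best_loss):
            best_acc = va
            best_loss = vl
            best = p.copy()
            hist.best_epoch = epoch
    return best, hist
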