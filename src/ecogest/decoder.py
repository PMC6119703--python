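"""Trained decoders: the recurrent sequence classifier and four baselines.

``rnn``           the LSTM sequence decoder (final-step readout).
``svm_global``    RBF SVM on band features from ONE window over the whole
                  analysis interval (the long-time-window decoder).
``svm_segments``  RBF SVM on the t x n sequence flattened to a vector.
``mlp_segments``  one-hidden-layer perceptron on the flattened sequence.
``lr_segments``   multinomial logistic regression on the flattened sequence.

All baselines standardize columns inside their pipeline; the SVM baselines
select C and gamma from the canonical grids by inner cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .lstm import LSTMParams, TrainConfig, TrainHistory, fit_lstm, lstm_forward
from .selection import SVM_C_GRID, SVM_GAMMA_GRID

BASELINE_KINDS = ("svm_global", "svm_segments", "mlp_segments", "lr_segments")


@dataclass
class DecoderConfig:
    """Decoder settings: LSTM size/schedule plus the validation fraction the
    recurrent decoder carves from its training data when no explicit
    validation set is supplied."""

    hidden_size: int = 32
    learning_rate: float = 1e-3
    lr_decay_per_epoch: float = 5e-4
    max_epochs: int = 200
    batch_size: int = 16
    val_fraction: float = 0.2
    seed: int = 0

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            hidden_size=self.hidden_size,
            learning_rate=self.learning_rate,
            lr_decay_per_epoch=self.lr_decay_per_epoch,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class TrainedDecoder:
    """A fitted decoder plus the provenance its predictions depend on."""

    kind: str  # "rnn" or a baseline kind
    classes: np.ndarray  # class labels in index order
    params: LSTMParams | None = None  # rnn only
    estimator: object | None = None  # sklearn pipeline, baselines only
    history: TrainHistory | None = None
    provenance: dict = dataclasses.field(default_factory=dict)
    input_shape: tuple[int, int] | None = None  # (t, n) per trial
    feature_mean: np.ndarray | None = None  # rnn z-scoring, fit on train
    feature_std: np.ndarray | None = None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_std

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.input_shape is not None and X.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match trained shape "
                f"{self.input_shape}"
            )
        if self.kind == "rnn":
            return lstm_forward(self._standardize(X), self.params)
        flat = X.reshape(X.shape[0], -1)
        return self.estimator.predict_proba(flat)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.input_shape is not None and X.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match trained shape "
                f"{self.input_shape}"
            )
        if self.kind == "rnn":
            idx = lstm_forward(self._standardize(X), self.params).argmax(axis=-1)
        else:
            flat = X.reshape(X.shape[0], -1)
            return self.estimator.predict(flat)
        return self.classes[idx]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def _encode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, enc = np.unique(np.asarray(y), return_inverse=True)
    return classes, enc


def train_decoder(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: DecoderConfig = DecoderConfig(),
    provenance: dict | None = None,
) -> TrainedDecoder:
    """Train the LSTM sequence decoder.

    When no validation split is given, ``cfg.val_fraction`` of the training
    trials (stratified) is held out; the returned parameters are the snapshot
    from the epoch with the best validation loss.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if X_val is None:
        rng = np.random.default_rng(cfg.seed)
        val_idx = _stratified_subset(y_train, cfg.val_fraction, rng)
        mask = np.zeros(len(y_train), dtype=bool)
        mask[val_idx] = True
        X_val, y_val = X_train[mask], y_train[mask]
        X_train, y_train = X_train[~mask], y_train[~mask]
    classes, enc_train = _encode(np.concatenate([y_train, y_val]))
    enc_tr = enc_train[: len(y_train)]
    enc_va = enc_train[len(y_train) :]
    # z-score each feature column (per segment position) on the training trials
    mean = X_train.mean(axis=0, keepdims=True)
    std = X_train.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    X_val = np.asarray(X_val, dtype=np.float64)
    params, hist = fit_lstm(
        (X_train - mean) / std, enc_tr, (X_val - mean) / std, enc_va,
        n_classes=len(classes), cfg=cfg.train_config(),
    )
    return TrainedDecoder(
        kind="rnn",
        classes=classes,
        params=params,
        history=hist,
        provenance=provenance or {},
        input_shape=X_train.shape[1:],
        feature_mean=mean,
        feature_std=std,
    )


def _stratified_subset(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a stratified subset with >= 1 sample per class."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * len(members))))
        idx.extend(rng.choice(members, size=k, replace=False))
    return np.sort(np.array(idx))


def train_baseline(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecoderConfig = DecoderConfig(),
    provenance: dict | None = None,
) -> TrainedDecoder:
    """Fit one of the comparison decoders on flattened feature vectors.

    ``svm_global`` expects single-window features (t = 1); the segment-based
    kinds expect the same t x n sequences as the recurrent decoder, reshaped
    into a single vector.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    flat = X.reshape(X.shape[0], -1)
    classes = np.unique(y)
    cv_folds = min(3, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    if kind in ("svm_global", "svm_segments"):
        cv = StratifiedKFold(n_splits=max(cv_folds, 2), shuffle=True,
                             random_state=cfg.seed)
        est = GridSearchCV(
            Pipeline(
                [("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))]
            ),
            {"svm__C": SVM_C_GRID, "svm__gamma": SVM_GAMMA_GRID},
            cv=cv,
        )
    elif kind == "mlp_segments":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(cfg.hidden_size,),
                        max_iter=500,
                        random_state=cfg.seed,
                    ),
                ),
            ]
        )
    else:  # lr_segments
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=1000, random_state=cfg.seed)),
            ]
        )
    est.fit(flat, y)
    return TrainedDecoder(
        kind=kind,
        classes=classes,
        estimator=est,
        provenance=provenance or {},
        input_shape=X.shape[1:],
    )


# ---------------------------------------------------------------------------
# Checkpoints: HDF5 weights + JSON provenance sidecar (rnn decoders)


def save_checkpoint(dec: TrainedDecoder, path) -> None:
    if dec.kind != "rnn":
        raise ValueError("checkpoints are defined for the rnn decoder")
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for name, arr in dec.params.arrays().items():
            g.create_dataset(name, data=arr)
        f.attrs["classes"] = [str(c) for c in dec.classes]
        f.attrs["provenance"] = json.dumps(dec.provenance)
        f.attrs["input_shape"] = list(dec.input_shape)
        if dec.feature_mean is not None:
            f.create_dataset("feature_mean", data=dec.feature_mean)
            f.create_dataset("feature_std", data=dec.feature_std)


def load_checkpoint(path) -> TrainedDecoder:
    with h5py.File(path, "r") as f:
        arrays = {name: f["weights"][name][()] for name in f["weights"]}
        params = LSTMParams(**arrays)
        return TrainedDecoder(
            kind="rnn",
            classes=np.array([str(c) for c in f.attrs["classes"]]),
            params=params,
            provenance=json.loads(f.attrs["provenance"]),
            input_shape=tuple(int(v) for v in f.attrs["input_shape"]),
            feature_mean=f["feature_mean"][()] if "feature_mean" in f else None,
            feature_std=f["feature_std"][()] if "feature_std" in f else None,
        )
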