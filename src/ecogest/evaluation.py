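"""Evaluation battery: permutation tests, paired t-tests, sweeps, and
mutual-information feature importance.

The permutation test here is the repeated-random-split protocol: each trial
draws a fresh (stratified) 10% test split, retrains every decoder on the
remaining 90%, and records its test accuracy.  Splits are shared across
decoders within a trial, so their accuracy vectors are paired and the classic
paired t-test applies to per-trial differences.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess
from .decoder import BASELINE_KINDS, DecoderConfig, TrainedDecoder, train_baseline, train_decoder

logger = logging.getLogger(__name__)

#: factory(X_train, y_train, seed) -> TrainedDecoder
DecoderFactory = Callable[[np.ndarray, np.ndarray, int], TrainedDecoder]


@dataclass
class EvalReport:
    """Aggregated evaluation results, serializable to JSON and TSV tables."""

    accuracy: dict[str, dict] = field(default_factory=dict)  # name -> mean/sd
    pairwise: list[dict] = field(default_factory=list)  # pair, t, p
    curves: list[dict] = field(default_factory=list)  # interval_ms, name, mean, sd
    mutual_info_bits: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seeds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def accuracy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"decoder": k, "mean": v["mean"], "sd": v["sd"]}
                for k, v in self.accuracy.items()
            ]
        )

    def pairwise_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise)

    def curves_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.curves)


def standard_factories(cfg: DecoderConfig = DecoderConfig()) -> dict[str, DecoderFactory]:
    """The five comparison decoders keyed by name.

    ``svm_global`` must be fed single-window features; the others take the
    segmented sequences.
    """

    def rnn(X, y, seed):
        c = dataclasses.replace(cfg, seed=seed)
        return train_decoder(X, y, cfg=c)

    factories: dict[str, DecoderFactory] = {"rnn": rnn}
    for kind in BASELINE_KINDS:
        def make(kind=kind):
            def f(X, y, seed):
                c = dataclasses.replace(cfg, seed=seed)
                return train_baseline(kind, X, y, cfg=c)
            return f
        factories[kind] = make()
    return factories


def _stratified_test_indices(
    y: np.ndarray, test_frac: float, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(test_frac * len(members))))
        if k >= len(members):
            raise ValueError("data too small for the requested test fraction")
        idx.extend(rng.choice(members, size=k, replace=False))
    return np.sort(np.array(idx))


def permutation_eval(
    factories: Mapping[str, DecoderFactory],
    datasets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    n_trials: int = 500,
    test_frac: float = 0.10,
    seed: int = 0,
    stratified: bool = True,
) -> dict[str, np.ndarray]:
    """Repeated random-split evaluation, paired across decoders.

    ``datasets`` maps each decoder name to its (X, y) representation; all
    label vectors must be identical so a single split applies to every
    decoder.  Returns one accuracy vector of length ``n_trials`` per decoder.
    """
    names = list(factories)
    ys = [np.asarray(datasets[n][1]) for n in names]
    for other in ys[1:]:
        if not np.array_equal(ys[0], other):
            raise ValueError("decoder datasets must share the same label vector")
    y = ys[0]
    rng = np.random.default_rng(seed)
    out = {n: np.empty(n_trials) for n in names}
    for t in range(n_trials):
        if stratified:
            test_idx = _stratified_test_indices(y, test_frac, rng)
        else:
            n_test = max(1, int(round(test_frac * len(y))))
            for _ in range(100):
                test_idx = rng.choice(len(y), size=n_test, replace=False)
                train_mask = np.ones(len(y), dtype=bool)
                train_mask[test_idx] = False
                if len(np.unique(y[test_idx])) == len(np.unique(y)) and len(
                    np.unique(y[train_mask])
                ) == len(np.unique(y)):
                    break
            else:
                raise ValueError("could not draw a split covering every class")
            logger.debug("plain random split drawn for trial %d", t)
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        trial_seed = int(rng.integers(2**31 - 1))
        for name in names:
            X, _ = datasets[name]
            dec = factories[name](X[mask], y[mask], trial_seed)
            out[name][t] = dec.accuracy(X[test_idx], y[test_idx])
    return out


def kfold_eval(
    factory: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int], TrainedDecoder],
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold accuracy with a per-fold validation split.

    Within each fold, ``val_fraction`` of the training trials (stratified) is
    set aside and handed to the factory, which uses it to pick
    hyperparameters (the recurrent decoder picks its early-stop epoch there);
    the fitted decoder is then scored on the fold's held-out test trials.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    accs = []
    for fold, (train_idx, test_idx) in enumerate(cv.split(X, y)):
        y_tr = y[train_idx]
        val_local = _stratified_test_indices(y_tr, val_fraction, rng)
        val_mask = np.zeros(len(train_idx), dtype=bool)
        val_mask[val_local] = True
        dec = factory(
            X[train_idx[~val_mask]],
            y_tr[~val_mask],
            X[train_idx[val_mask]],
            y_tr[val_mask],
            int(rng.integers(2**31 - 1)),
        )
        accs.append(dec.accuracy(X[test_idx], y[test_idx]))
    return np.array(accs)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on per-trial accuracy differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 samples")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def hidden_unit_sweep(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    sizes: Sequence[int] = (8, 16, 32, 64, 128),
    cfg: DecoderConfig = DecoderConfig(),
    n_seeds: int = 3,
) -> tuple[dict[int, tuple[float, float]], int]:
    """Validation accuracy mean +/- sd per hidden size; returns (table, best).

    Ties break toward the smallest size.
    """
    table: dict[int, tuple[float, float]] = {}
    for size in sizes:
        accs = []
        for s in range(n_seeds):
            c = dataclasses.replace(cfg, hidden_size=size, seed=cfg.seed + s)
            dec = train_decoder(X_train, y_train, X_val, y_val, cfg=c)
            accs.append(dec.accuracy(X_val, y_val))
        table[size] = (float(np.mean(accs)), float(np.std(accs)))
    best = min(sorted(table), key=lambda s: (-table[s][0], s))
    return table, best


def rapid_eval_sweep(
    rec,
    onsets: dict[int, float],
    factories: Mapping[str, DecoderFactory],
    intervals_ms: Sequence[float] = tuple(range(100, 1300, 100)),
    n_trials: int = 20,
    seed: int = 0,
    partition: preprocess.BandPartition = preprocess.BandPartition(),
    welch_cfg: preprocess.WelchConfig = preprocess.WelchConfig(),
    feature_indices: Sequence[int] | None = None,
) -> EvalReport:
    """Latency-accuracy tradeoff: permutation-evaluate each decoder on
    features rebuilt for each post-onset interval under the rapid plan.

    ``svm_global`` (if present) gets single-window features over the same
    interval.  Intervals longer than the shortest epoch are skipped with a
    warning.
    """
    report = EvalReport(n_permutations=n_trials, seeds=[seed])
    for t_ms in intervals_ms:
        plan = preprocess.rapid_window_plan(t_ms)
        base_plan = preprocess.SegmentPlan(
            window_ms=plan.window_ms,
            stride_ms=plan.window_ms / 2,  # 50% overlap; rapid strides explode
            n_segments=plan.n_segments,
        )
        try:
            ds = preprocess.session_features(
                rec, onsets, plan, partition, welch_cfg, baseline_plan=base_plan
            )
        except ValueError as err:
            logger.warning("interval %g ms skipped: %s", t_ms, err)
            continue
        X_seq = ds.X if feature_indices is None else ds.X[:, :, list(feature_indices)]
        datasets = {}
        for name in factories:
            if name == "svm_global":
                g = preprocess.global_window_features(
                    rec, onsets, interval_ms=t_ms, partition=partition,
                    welch_cfg=welch_cfg,
                )
                Xg = (
                    g.X if feature_indices is None
                    else g.X[:, :, list(feature_indices)]
                )
                datasets[name] = (Xg, g.y)
            else:
                datasets[name] = (X_seq, ds.y)
        accs = permutation_eval(factories, datasets, n_trials, seed=seed)
        for name, vec in accs.items():
            report.curves.append(
                {
                    "interval_ms": float(t_ms),
                    "decoder": name,
                    "mean": float(vec.mean()),
                    "sd": float(vec.std(ddof=1)) if len(vec) > 1 else 0.0,
                }
            )
    return report


def mutual_info(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 8
) -> float:
    """Plug-in mutual information (bits) between a feature and the labels.

    The feature is discretized into ``n_bins`` quantile bins; a constant
    feature has zero information.  No bias correction is applied.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if x.shape != y.shape:
        raise ValueError("feature/labels length mismatch")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    xb = np.digitize(x, edges)
    joint = pd.crosstab(xb, y).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def mutual_info_profile(
    X: np.ndarray, y: np.ndarray, feature_names: Sequence[str], n_bins: int = 8
) -> dict[str, float]:
    """MI of each feature (averaged over time segments) to the labels."""
    return {
        name: mutual_info(X[:, :, j].mean(axis=1), y, n_bins)
        for j, name in enumerate(feature_names)
    }
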