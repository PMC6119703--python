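"""Band-power feature extraction with relax-baseline normalization.

Pipeline per trial: spatial referencing -> sliding-window segmentation anchored
at movement onset -> Welch PSD per segment -> division by the mean relax-stage
PSD (per channel and frequency bin) -> averaging of the normalized PSD within
five canonical frequency bands.  A trial becomes a ``t x n`` matrix: ``t``
temporal segments by ``n = n_channels x n_bands`` dimensionless band-power
features, the input sequence for the decoders.

The default plan is a 300 ms window sliding with a 100 ms stride, 10 segments,
so the analysis interval is 1.2 s after onset.  For shorter intervals the
rapid plan rescales the stride as (t - w)/9 (and halves the window when the
interval is under 300 ms) so that 10 segments always tile the interval exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import EventTable, Recording, TrialEpoch, relax_intervals

logger = logging.getLogger(__name__)

#: The five canonical bands: low-frequency, beta, low gamma, high gamma, high.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("4-12", 4.0, 12.0),
    ("12-40", 12.0, 40.0),
    ("40-70", 40.0, 70.0),
    ("70-135", 70.0, 135.0),
    ("135-200", 135.0, 200.0),
)


@dataclass(frozen=True)
class SegmentPlan:
    """Sliding-window segmentation plan, anchored at movement onset.

    Window starts are ``round(i * stride * fs)`` samples from the anchor, which
    keeps non-integer strides (rapid plans) bit-reproducible.
    """

    window_ms: float = 300.0
    stride_ms: float = 100.0
    n_segments: int = 10

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.stride_ms < 0:
            raise ValueError("stride_ms must be >= 0")

    @property
    def coverage_ms(self) -> float:
        """Total analysis interval: last window end relative to the anchor."""
        return (self.n_segments - 1) * self.stride_ms + self.window_ms

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def starts(self, fs: float) -> np.ndarray:
        return np.array(
            [int(round(i * self.stride_ms * fs / 1000.0)) for i in range(self.n_segments)]
        )


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings: Hann window, 50% overlap, detrending off.

    ``nfft`` is held fixed so the frequency grid does not change when a short
    segment forces a smaller effective sub-segment (``nperseg`` is capped at
    the segment length by :meth:`for_length`).
    """

    nperseg: int = 256
    nfft: int = 256
    window: str = "hann"
    detrend: bool | str = False

    def for_length(self, n_samples: int) -> "WelchConfig":
        if n_samples >= self.nperseg:
            return self
        return dataclasses.replace(self, nperseg=n_samples)


@dataclass(frozen=True)
class BandPartition:
    """Ordered, non-overlapping frequency bands; bins assigned half-open [lo, hi)."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for label, lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"band {label}: lo must be < hi")
        edges = sorted((lo, hi) for _, lo, hi in self.bands)
        for (_, hi_prev), (lo_next, _) in zip(edges, edges[1:]):
            if lo_next < hi_prev:
                raise ValueError("bands overlap")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bands]

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class PSDMatrix:
    """One-sided PSD per channel on a shared frequency grid (power per Hz)."""

    values: np.ndarray  # channels x frequency bins
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.values.shape[-1] != self.freqs.shape[0]:
            raise ValueError("values/freqs length mismatch")
        if (np.diff(self.freqs) <= 0).any():
            raise ValueError("freqs must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError("PSD values must be nonnegative")


@dataclass
class BaselineStats:
    """Mean relax-stage PSD per channel and frequency bin."""

    mean_psd: np.ndarray  # channels x frequency bins
    freqs: np.ndarray
    n_relax_segments: int


def reference_filter(rec: Recording, mode: str = "session_mean") -> Recording:
    """Spatial referencing.

    ``session_mean`` subtracts each channel's whole-session temporal mean
    (the default); ``car`` subtracts the instantaneous cross-channel mean
    (common average reference).
    """
    if mode == "session_mean":
        out = rec.signal - rec.signal.mean(axis=1, keepdims=True)
    elif mode == "car":
        if rec.n_channels < 2:
            raise ValueError("car referencing requires >= 2 channels")
        out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown reference mode: {mode!r}")
    return Recording(out, rec.fs, rec.channel_ids, rec.events)


def segment_epoch(epoch: TrialEpoch, plan: SegmentPlan) -> list[np.ndarray]:
    """Divide an onset-anchored epoch into the plan's sliding windows."""
    return segment_array(epoch.signal, epoch.fs, plan)


def segment_array(signal: np.ndarray, fs: float, plan: SegmentPlan) -> list[np.ndarray]:
    length = plan.window_samples(fs)
    starts = plan.starts(fs)
    needed = int(starts[-1]) + length
    if needed > signal.shape[1]:
        raise ValueError(
            f"epoch too short for plan: needs {needed / fs:.3f} s, "
            f"has {signal.shape[1] / fs:.3f} s"
        )
    return [signal[:, s : s + length] for s in starts]


def welch_psd(segment: np.ndarray, fs: float, cfg: WelchConfig = WelchConfig()) -> PSDMatrix:
    """One-sided Welch PSD of a channels x samples segment."""
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    if segment.shape[1] < cfg.nperseg:
        raise ValueError(
            f"segment of {segment.shape[1]} samples is shorter than the Welch "
            f"sub-segment ({cfg.nperseg}); cap nperseg with WelchConfig.for_length"
        )
    freqs, pxx = sps.welch(
        segment,
        fs=fs,
        window=cfg.window,
        nperseg=cfg.nperseg,
        noverlap=cfg.nperseg // 2,
        nfft=max(cfg.nfft, cfg.nperseg),
        detrend=cfg.detrend,
        axis=1,
        scaling="density",
    )
    return PSDMatrix(values=pxx, freqs=freqs)


def baseline_mean(relax_psds: Sequence[PSDMatrix]) -> BaselineStats:
    """Element-wise mean of the relax-stage PSD matrices."""
    if len(relax_psds) == 0:
        raise ValueError("need at least one relax segment for a baseline")
    freqs = relax_psds[0].freqs
    for p in relax_psds[1:]:
        if p.freqs.shape != freqs.shape or not np.array_equal(p.freqs, freqs):
            raise ValueError("relax PSDs computed on inconsistent frequency grids")
    stack = np.stack([p.values for p in relax_psds])
    return BaselineStats(
        mean_psd=stack.mean(axis=0), freqs=freqs, n_relax_segments=len(relax_psds)
    )


def normalize_psd(
    task: PSDMatrix,
    base: BaselineStats,
    partition: BandPartition | None = None,
) -> PSDMatrix:
    """Divide a task-segment PSD by the baseline mean, bin by bin.

    The result is dimensionless relative power.  When ``partition`` is given,
    only bins inside its analysis bands must have a positive baseline;
    otherwise every bin is checked.
    """
    if task.freqs.shape != base.freqs.shape or not np.array_equal(task.freqs, base.freqs):
        raise ValueError("task/baseline frequency grids differ")
    if partition is None:
        check = np.ones_like(base.freqs, dtype=bool)
    else:
        check = np.zeros_like(base.freqs, dtype=bool)
        for _, lo, hi in partition.bands:
            check |= (base.freqs >= lo) & (base.freqs < hi)
    if (base.mean_psd[:, check] <= 0).any():
        raise ValueError("baseline PSD is non-positive on an analysis bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(base.mean_psd > 0, task.values / base.mean_psd, 0.0)
    return PSDMatrix(values=values, freqs=task.freqs)


def band_aggregate(norm: PSDMatrix, partition: BandPartition = BandPartition()) -> np.ndarray:
    """Average the normalized PSD within each band: channels x bands."""
    out = np.empty((norm.values.shape[0], partition.n_bands))
    for j, (label, lo, hi) in enumerate(partition.bands):
        mask = (norm.freqs >= lo) & (norm.freqs < hi)
        if not mask.any():
            df = np.median(np.diff(norm.freqs))
            raise ValueError(
                f"band {label} contains no frequency bins "
                f"(grid resolution {df:.3f} Hz)"
            )
        out[:, j] = norm.values[:, mask].mean(axis=1)
    return out


def rapid_window_plan(t_interval_ms: float) -> SegmentPlan:
    """Segmentation plan for a post-onset interval of ``t`` milliseconds.

    For t >= 300 the window stays 300 ms and the stride is (t - 300)/9; for
    t < 300 the window shrinks to t/2 with stride (t/2)/9.  Ten segments
    always tile [0, t] exactly (up to sample rounding); at t = 300 the stride
    degenerates to 0 and the ten windows coincide.
    """
    if not (100.0 <= t_interval_ms <= 1200.0):
        raise ValueError("interval must be within [100, 1200] ms")
    if t_interval_ms >= 300.0:
        window = 300.0
        stride = (t_interval_ms - 300.0) / 9.0
    else:
        window = t_interval_ms / 2.0
        stride = window / 9.0
    if stride == 0.0:
        logger.info("rapid plan at t = %g ms is degenerate (stride 0)", t_interval_ms)
    return SegmentPlan(window_ms=window, stride_ms=stride, n_segments=10)


# ---------------------------------------------------------------------------
# Session-level feature extraction


@dataclass
class FeatureDataset:
    """Per-trial band-feature sequences: X is (n_trials, t, n_features)."""

    X: np.ndarray
    y: np.ndarray  # per-trial labels
    feature_names: list[str]  # "ch<k>_band<label>", channel-major
    trial_ids: np.ndarray
    plan: SegmentPlan
    partition: BandPartition

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_segments(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[2]

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for i in range(self.n_trials):
            for s in range(self.n_segments):
                rows.append(
                    {
                        "trial_id": int(self.trial_ids[i]),
                        "segment_idx": s,
                        **dict(zip(self.feature_names, self.X[i, s])),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def feature_names(channel_ids: Sequence[str], partition: BandPartition) -> list[str]:
    return [f"ch{c}_band{b}" for c in channel_ids for b in partition.labels]


def session_baseline(
    rec: Recording,
    plan: SegmentPlan,
    welch_cfg: WelchConfig = WelchConfig(),
    partition: BandPartition = BandPartition(),
) -> BaselineStats:
    """Mean relax-stage PSD over all relax intervals of the session.

    Relax intervals are tiled with the same window/stride as the task stage,
    taking every full window that fits.
    """
    length = plan.window_samples(rec.fs)
    stride = int(round(plan.stride_ms * rec.fs / 1000.0))
    if stride < 1:
        stride = length  # degenerate (stride-0) plans tile relax back-to-back
    cfg = welch_cfg.for_length(length)
    psds: list[PSDMatrix] = []
    for t0, t1 in relax_intervals(rec.events, rec.duration):
        i0 = int(round(t0 * rec.fs))
        i1 = int(round(t1 * rec.fs))
        for start in range(i0, i1 - length + 1, stride):
            psds.append(welch_psd(rec.signal[:, start : start + length], rec.fs, cfg))
    if not psds:
        raise ValueError("no relax segments available for the baseline")
    return baseline_mean(psds)


def epoch_features(
    epoch: TrialEpoch,
    base: BaselineStats,
    plan: SegmentPlan,
    partition: BandPartition = BandPartition(),
    welch_cfg: WelchConfig = WelchConfig(),
) -> np.ndarray:
    """The trial's t x (channels*bands) normalized band-feature sequence."""
    cfg = welch_cfg.for_length(plan.window_samples(epoch.fs))
    rows = []
    for seg in segment_epoch(epoch, plan):
        psd = welch_psd(seg, epoch.fs, cfg)
        norm = normalize_psd(psd, base, partition)
        rows.append(band_aggregate(norm, partition).reshape(-1))
    return np.stack(rows)


def session_features(
    rec: Recording,
    onsets: dict[int, float],
    plan: SegmentPlan = SegmentPlan(),
    partition: BandPartition = BandPartition(),
    welch_cfg: WelchConfig = WelchConfig(),
    reference: str | None = "session_mean",
    baseline_plan: SegmentPlan | None = None,
) -> FeatureDataset:
    """Full pipeline: reference -> baseline -> per-trial feature sequences.

    ``baseline_plan`` overrides the window/stride used to tile the relax
    stages (by default the task plan itself); rapid plans with near-zero
    strides should pass a 50%-overlap baseline plan instead.
    """
    from .io import extract_trials

    if reference is not None:
        rec = reference_filter(rec, reference)
    base = session_baseline(rec, baseline_plan or plan, welch_cfg, partition)
    epochs = extract_trials(rec, onsets)
    X, y, tids = [], [], []
    needed = plan.coverage_ms / 1000.0
    for ep in epochs:
        if ep.duration < needed:
            logger.warning(
                "trial %d epoch (%.3f s) shorter than plan coverage (%.3f s); skipped",
                ep.trial_id, ep.duration, needed,
            )
            continue
        X.append(epoch_features(ep, base, plan, partition, welch_cfg))
        y.append(ep.label)
        tids.append(ep.trial_id)
    if not X:
        raise ValueError("no trial produced features")
    return FeatureDataset(
        X=np.stack(X),
        y=np.asarray(y),
        trial_ids=np.asarray(tids),
        feature_names=feature_names(rec.channel_ids, partition),
        plan=plan,
        partition=partition,
    )


def global_window_features(
    rec: Recording,
    onsets: dict[int, float],
    interval_ms: float = 1200.0,
    partition: BandPartition = BandPartition(),
    welch_cfg: WelchConfig = WelchConfig(),
    reference: str | None = "session_mean",
) -> FeatureDataset:
    """Single-window features over the whole analysis interval (t = 1).

    This is the representation of the long-time-window decoder: one Welch PSD
    per trial over [onset, onset + interval], baseline-normalized and
    band-aggregated exactly like the segmented features.
    """
    plan = SegmentPlan(window_ms=interval_ms, stride_ms=0.0, n_segments=1)
    return session_features(rec, onsets, plan, partition, welch_cfg, reference)
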