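"""Synthetic ECoG-like sessions with planted, gesture-conditioned band power.

The generator emulates the structure of a cued gesture task: alternating relax
(2-2.5 s) and task (2-3 s) stages, three gesture classes, 32 channels sampled
at 2 kHz, and a 14-sensor data-glove trace whose flexion ramp marks the motion
onset a short delay after the gesture cue.

Background activity is Gaussian 1/f^alpha noise per channel plus a 50 Hz line
component.  Gesture information is planted as band-limited noise carriers added
on a small subset of channels inside the high-gamma (70-135 Hz) and high
(135-200 Hz) bands: during [onset, cue_stop] the expected band power on a
planted (channel, band) is multiplied by a class- and time-dependent gain
``1 + (effect_size - 1) * m * env(t)``.  Because powers of independent signals
add, the task/relax band-power ratio measured by the Welch pipeline equals the
planted gain in expectation; ``effect_size = 1`` plants nothing.

Two envelope regimes:

``decay``
    Gain ramps up over 100 ms after onset, then decays linearly to 50% by 1 s
    (an early-peaking power time course); classes differ by a multiplicative
    level per (class, feature), so class information lives in the magnitude of
    the band-power response.

``order``
    All classes reach the same peak gain, but the gain bump's *timing* is
    class-specific (feature group A early vs. late vs. middle, group B the
    mirror image), with a per-trial latency jitter shared by all features.
    Time-averaged power is matched across classes, so only the temporal
    ordering of the response distinguishes gestures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import EventTable, GloveRecording, Recording

GESTURES = ("rock", "scissors", "paper")

#: Per-(class, feature) modulation levels for the "decay" regime: feature j
#: uses the j-th permutation of the level triple, so successive planted
#: features order the classes differently and each adds non-redundant
#: class information.
_DECAY_LEVELS = tuple(itertools.permutations((1.0, 0.55, 0.25)))

#: The "order" regime: per trial, the power bump of feature group A sits at a
#: uniformly random position in the analysis window and group B's bump is
#: circularly lagged by a class-specific offset (seconds).  Both bump-center
#: marginals are uniform for every class, so only the relative timing of the
#: two groups carries class information.
_ORDER_LAGS = (0.3, -0.3, 0.0)
_ORDER_SIGMA = 0.08
_ORDER_SPAN = (0.1, 1.1)  # bump centers live on this circular interval


class InsufficientDataError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator settings; the defaults mirror the acquisition protocol
    (2 kHz sampling, 32 channels, 2-2.5 s relax, 2-3 s task, 3 gestures,
    one 150-trial session)."""

    n_channels: int = 32
    fs: float = 2000.0
    n_trials: int = 150
    n_classes: int = 3
    relax_dur_range: tuple[float, float] = (2.0, 2.5)
    task_dur_range: tuple[float, float] = (2.0, 3.0)
    informative_channels: tuple[int, ...] = (3, 11)
    informative_bands: tuple[str, ...] = ("70-135", "135-200")
    effect_size: float = 3.0
    envelope_shape: str = "decay"  # "decay" | "order"
    noise_exponent: float = 1.0
    line_noise_hz: float = 50.0
    line_noise_amp: float = 0.5  # relative to background RMS
    background_rms: float = 10.0  # microvolt-scale
    onset_delay_range: tuple[float, float] = (0.1, 0.3)
    glove_n_sensors: int = 14
    glove_threshold: float = 5e-4  # flexion units per sample; ramp slope is 2x
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < self.n_classes:
            raise InsufficientDataError(
                f"n_trials ({self.n_trials}) < n_classes ({self.n_classes})"
            )
        for c in self.informative_channels:
            if not (0 <= c < self.n_channels):
                raise ValueError(f"informative channel {c} out of range")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        for name, (lo, hi) in (
            ("relax_dur_range", self.relax_dur_range),
            ("task_dur_range", self.task_dur_range),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        if self.envelope_shape not in ("decay", "order"):
            raise ValueError(f"unknown envelope_shape {self.envelope_shape!r}")
        if self.envelope_shape == "order" and self.n_classes != 3:
            raise ValueError("the order-coded regime is defined for 3 classes")

    def band_edges(self, label: str) -> tuple[float, float]:
        lo, hi = label.split("-")
        return float(lo), float(hi)

    def class_labels(self) -> list[str]:
        if self.n_classes == 3:
            return list(GESTURES)
        return [f"g{k}" for k in range(self.n_classes)]


@dataclass
class GroundTruth:
    """What was planted: labels, onsets, informative features, envelopes."""

    labels: np.ndarray  # per-trial class label (str)
    onset_times: np.ndarray  # seconds
    planted_features: set[tuple[int, str]]
    class_envelopes: np.ndarray  # (n_classes, n_planted, grid) gain courses
    envelope_grid: np.ndarray  # seconds after onset


def _colored_profile(n: int, fs: float, alpha: float) -> np.ndarray:
    """rFFT amplitude profile for 1/f^alpha noise; DC removed."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    return amp


def _profile_variance(amp: np.ndarray, n: int) -> float:
    """Per-sample variance of irfft(rfft(white) * amp) for unit white noise."""
    weights = np.full(amp.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return float((weights * amp**2).sum() / n)


def _band_power_fraction(amp: np.ndarray, n: int, fs: float, lo: float, hi: float) -> float:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    weights = np.full(amp.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    total = (weights * amp**2).sum()
    mask = (freqs >= lo) & (freqs < hi)
    return float((weights * amp**2)[mask].sum() / total)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance (in expectation) Gaussian noise confined to [lo, hi) Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = ((freqs >= lo) & (freqs < hi)).astype(float)
    spec = np.fft.rfft(rng.standard_normal(n)) * mask
    x = np.fft.irfft(spec, n)
    var = _profile_variance(mask, n)
    if var <= 0:
        raise ValueError(f"band [{lo}, {hi}) Hz holds no spectral mass at fs={fs}")
    return x / np.sqrt(var)


def _decay_envelope(t: np.ndarray) -> np.ndarray:
    """Ramp to 1 over 100 ms, decay linearly to 0.5 by 1 s, hold at 0.5."""
    env = np.zeros_like(t)
    rising = (t >= 0) & (t < 0.1)
    env[rising] = t[rising] / 0.1
    decaying = (t >= 0.1) & (t < 1.0)
    env[decaying] = 1.0 - 0.5 * (t[decaying] - 0.1) / 0.9
    env[t >= 1.0] = 0.5
    return env


def _order_envelope(t: np.ndarray, class_idx: int, group: int, phase: float) -> np.ndarray:
    lo, hi = _ORDER_SPAN
    span = hi - lo
    offset = phase if group == 0 else (phase + _ORDER_LAGS[class_idx] / span) % 1.0
    center = lo + offset * span
    env = np.exp(-0.5 * ((t - center) / _ORDER_SIGMA) ** 2)
    env[t < 0] = 0.0
    return env


def _planted_gain(
    cfg: SynthConfig, class_idx: int, feature_idx: int, t: np.ndarray, phase: float
) -> np.ndarray:
    """Time course of the power gain g(t) >= 1 on one planted feature."""
    if cfg.envelope_shape == "decay":
        level = _DECAY_LEVELS[feature_idx % len(_DECAY_LEVELS)][class_idx]
        env = level * _decay_envelope(t)
    else:
        env = _order_envelope(t, class_idx, feature_idx % 2, phase)
    return 1.0 + (cfg.effect_size - 1.0) * env


def _glove_noise(rng: np.random.Generator, shape: tuple[int, int], max_step: float) -> np.ndarray:
    """Smooth sensor noise whose first difference never exceeds ``max_step``."""
    raw = rng.standard_normal(shape)
    kernel = np.ones(50) / 50.0
    smooth = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 1, raw)
    step = np.abs(np.diff(smooth, axis=1)).max()
    if step > 0:
        smooth *= max_step / step
    return smooth


def _glove_ramp(n_samples: int, onset_sample: int, stop_sample: int, slope: float) -> np.ndarray:
    """Flexion ramp: first moved sample AT onset_sample, rise to 1, release."""
    x = np.zeros(n_samples)
    j = np.arange(n_samples - onset_sample)
    x[onset_sample:] = np.minimum((j + 1) * slope, 1.0)
    # release over 0.3 s worth of the same slope after the stop cue
    if stop_sample < n_samples:
        k = np.arange(n_samples - stop_sample)
        x[stop_sample:] = np.maximum(x[stop_sample:] - (k + 1) * slope, 0.0)
    return x


def generate_glove(
    onset_time: float,
    cfg: SynthConfig,
    duration: float | None = None,
    stop_time: float | None = None,
    rng: np.random.Generator | None = None,
    ramp_amplitude: float = 1.0,
) -> GloveRecording:
    """A standalone glove trace with a single flexion ramp starting at onset.

    The composite sensor (index 0) carries the ramp with per-sample slope twice
    ``cfg.glove_threshold``; all sensors carry smooth noise whose derivative
    stays below a quarter of the threshold, so onset detection at the default
    threshold is exact.  ``ramp_amplitude = 0`` yields a rampless trace.
    """
    if onset_time <= 0:
        raise ValueError("onset_time must be positive")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if duration is None:
        duration = onset_time + 2.0
    n = int(round(duration * cfg.fs))
    onset_sample = int(round(onset_time * cfg.fs))
    if onset_sample >= n:
        raise ValueError("onset_time outside the trace")
    stop_sample = int(round(stop_time * cfg.fs)) if stop_time is not None else n
    flex = _glove_noise(rng, (cfg.glove_n_sensors, n), cfg.glove_threshold / 4.0)
    slope = 2.0 * cfg.glove_threshold
    flex[0] += ramp_amplitude * _glove_ramp(n, onset_sample, stop_sample, slope)
    return GloveRecording(flexion=flex, fs=cfg.fs)


def generate_session(cfg: SynthConfig) -> tuple[Recording, GloveRecording, GroundTruth]:
    """Generate one task session: recording + glove + ground truth.

    The recording alternates relax and task stages with cue_start/cue_stop
    events per trial; each planted (channel, band) carries the configured
    class- and time-dependent power gain between motion onset and cue stop,
    while non-planted channels are statistically identical across classes.
    """
    rng = np.random.default_rng(cfg.seed)
    labels_pool = cfg.class_labels()

    # balanced label sequence, shuffled
    reps = int(np.ceil(cfg.n_trials / cfg.n_classes))
    labels = np.array((labels_pool * reps)[: cfg.n_trials])
    rng.shuffle(labels)

    relax_dur = rng.uniform(*cfg.relax_dur_range, size=cfg.n_trials)
    task_dur = rng.uniform(*cfg.task_dur_range, size=cfg.n_trials)
    onset_delay = rng.uniform(*cfg.onset_delay_range, size=cfg.n_trials)
    # per-trial bump phase for the order regime (uniform; class-independent)
    phases = (
        rng.uniform(0.0, 1.0, size=cfg.n_trials)
        if cfg.envelope_shape == "order"
        else np.zeros(cfg.n_trials)
    )

    cue_start = np.cumsum(relax_dur) + np.concatenate(([0.0], np.cumsum(task_dur)[:-1]))
    cue_stop = cue_start + task_dur
    onsets = cue_start + onset_delay
    duration = cue_stop[-1] + 0.25
    n = int(round(duration * cfg.fs))

    # background: per-channel 1/f^alpha noise scaled to background_rms, + line
    amp = _colored_profile(n, cfg.fs, cfg.noise_exponent)
    scale = cfg.background_rms / np.sqrt(_profile_variance(amp, n))
    signal = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        spec = np.fft.rfft(rng.standard_normal(n)) * amp
        signal[c] = np.fft.irfft(spec, n) * scale
    if cfg.line_noise_amp > 0:
        tt = np.arange(n) / cfg.fs
        line_phase = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        line = cfg.line_noise_amp * cfg.background_rms
        signal += line * np.sin(
            2 * np.pi * cfg.line_noise_hz * tt[None, :] + line_phase[:, None]
        )

    # planted carriers during [onset, cue_stop) on informative (channel, band)
    planted = [
        (ch, band) for ch in cfg.informative_channels for band in cfg.informative_bands
    ]
    band_power = {
        band: _band_power_fraction(amp, n, cfg.fs, *cfg.band_edges(band))
        * cfg.background_rms**2
        for band in cfg.informative_bands
    }
    class_index = {lab: k for k, lab in enumerate(labels_pool)}
    for i in range(cfg.n_trials):
        k = class_index[labels[i]]
        i0 = int(round(onsets[i] * cfg.fs))
        i1 = int(round(cue_stop[i] * cfg.fs))
        t_rel = (np.arange(i0, i1) - i0) / cfg.fs
        for j, (ch, band) in enumerate(planted):
            gain = _planted_gain(cfg, k, j, t_rel, phases[i])
            extra = np.clip(gain - 1.0, 0.0, None) * band_power[band]
            if not extra.any():
                continue
            carrier = _bandlimited_noise(rng, i1 - i0, cfg.fs, *cfg.band_edges(band))
            signal[ch, i0:i1] += np.sqrt(extra) * carrier

    # glove: composite-sensor ramp per trial over session-long smooth noise
    flex = _glove_noise(
        rng, (cfg.glove_n_sensors, n), cfg.glove_threshold / 4.0
    )
    slope = 2.0 * cfg.glove_threshold
    for i in range(cfg.n_trials):
        i0 = int(round(onsets[i] * cfg.fs))
        i1 = int(round(cue_stop[i] * cfg.fs))
        flex[0] += _glove_ramp(n, i0, i1, slope)

    rows = []
    for i in range(cfg.n_trials):
        rows.append((i, "cue_start", cue_start[i], labels[i]))
        rows.append((i, "onset", onsets[i], ""))
        rows.append((i, "cue_stop", cue_stop[i], ""))
    events = EventTable.from_rows(rows)

    rec = Recording(
        signal=signal,
        fs=cfg.fs,
        channel_ids=[str(c) for c in range(cfg.n_channels)],
        events=events,
    )
    glove = GloveRecording(flexion=flex, fs=cfg.fs)

    grid = np.arange(0.0, 1.2 + 1e-9, 0.01)
    envs = np.empty((cfg.n_classes, len(planted), grid.size))
    for k in range(cfg.n_classes):
        for j in range(len(planted)):
            envs[k, j] = _planted_gain(cfg, k, j, grid, 0.0)
    truth = GroundTruth(
        labels=labels,
        onset_times=onsets,
        planted_features=set(planted),
        class_envelopes=envs,
        envelope_grid=grid,
    )
    return rec, glove, truth
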