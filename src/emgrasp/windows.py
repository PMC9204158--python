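"""Sliding windows over envelopes and per-channel RMS/MAV/VAR features.

Windows are T = 320 ms long with a 40 ms step.  At fs = 1562.5 Hz the step is
62.5 samples: start indices are computed in milliseconds and floored per
window, so the mean step stays exactly 62.5 samples with no cumulative drift.
Each window takes the phase of its center sample and the corresponding label
(the trial gesture on motional phases, 0 at rest).  The feature vector
concatenates per-channel blocks in the fixed order [RMS_1..C, MAV_1..C,
VAR_1..C], giving 3C = 36 values for the 12-channel montage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, EnvelopeRecording, MOTIONAL_PHASES, REST_LABEL

__all__ = [
    "WindowConfig",
    "Window",
    "window_samples",
    "window_starts",
    "slide",
    "rms",
    "mav",
    "var",
    "featurize",
    "feature_names",
    "feature_table",
]


@dataclass(frozen=True)
class WindowConfig:
    window_ms: float = 320.0
    step_ms: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.step_ms <= self.window_ms:
            raise ConfigurationError("require 0 < step_ms <= window_ms")


@dataclass
class Window:
    """One windowed slice of a trial with its provenance tags."""

    samples: np.ndarray  # (C, T_samples)
    start_ms: float
    start_idx: int
    center_ms: float = 0.0
    trial_id: str = ""
    phase: str | None = None
    label: int | None = None


def window_samples(window_ms: float, fs: float) -> int:
    return int(round(window_ms * fs / 1000.0))


def window_starts(n_samples: int, fs: float, cfg: WindowConfig) -> np.ndarray:
    """Start indices floor(k * step_ms * fs / 1000) while the window fits."""
    t = window_samples(cfg.window_ms, fs)
    starts = []
    k = 0
    while True:
        s = math.floor(k * cfg.step_ms * fs / 1000.0)
        if s + t > n_samples:
            break
        starts.append(s)
        k += 1
    return np.asarray(starts, dtype=int)


def _label_for(phase: str | None, gesture: int | None) -> int | None:
    if phase is None:
        return None
    if phase in MOTIONAL_PHASES:
        if gesture is None:
            raise ValueError("gesture label required to tag motional windows")
        return int(gesture)
    return REST_LABEL


def slide(
    env: EnvelopeRecording,
    cfg: WindowConfig,
    timeline=None,
    gesture: int | None = None,
    trial_id: str = "",
) -> list[Window]:
    """Cut a trial into overlapping windows, tagged by their center phase.

    ``timeline`` is anything with a ``phase_at(t_ms)`` method (a ground-truth
    ``PhaseTimeline`` or a fitted ``SegmentedTrial``).  A trial shorter than
    one window yields an empty list with a warning.
    """
    t = window_samples(cfg.window_ms, env.fs)
    starts = window_starts(env.n_samples, env.fs, cfg)
    if starts.size == 0:
        warnings.warn(
            f"trial of {env.n_samples} samples shorter than one {cfg.window_ms} ms window",
            stacklevel=2,
        )
        return []
    out = []
    for k, s in enumerate(starts):
        start_ms = k * cfg.step_ms
        center_ms = start_ms + cfg.window_ms / 2.0
        phase = timeline.phase_at(center_ms) if timeline is not None else None
        out.append(
            Window(
                samples=env.samples[:, s:s + t],
                start_ms=start_ms,
                start_idx=int(s),
                center_ms=center_ms,
                trial_id=trial_id,
                phase=phase,
                label=_label_for(phase, gesture),
            )
        )
    return out


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return x


def rms(x: np.ndarray) -> float:
    """Root mean square sqrt(mean(x^2))."""
    x = _check_window(x)
    return float(np.sqrt(np.mean(np.square(x))))


def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    x = _check_window(x)
    return float(np.mean(np.abs(x)))


def var(x: np.ndarray) -> float:
    """Population variance mean((x - mean(x))^2)."""
    x = _check_window(x)
    return float(np.mean(np.square(x - np.mean(x))))


def feature_names(channel_names: tuple[str, ...]) -> list[str]:
    """Column order contract: rms block, mav block, var block."""
    return [f"{feat}_{ch}" for feat in ("rms", "mav", "var") for ch in channel_names]


def _features_from_blocks(blocks: np.ndarray) -> np.ndarray:
    """(n, C, T) window stack -> (n, 3C) feature matrix."""
    r = np.sqrt(np.mean(np.square(blocks), axis=2))
    m = np.mean(np.abs(blocks), axis=2)
    mu = np.mean(blocks, axis=2)
    v = np.mean(np.square(blocks - mu[:, :, None]), axis=2)
    return np.concatenate([r, m, v], axis=1)


def featurize(w: Window) -> np.ndarray:
    """Length-3C feature vector of one window."""
    return _features_from_blocks(w.samples[None, :, :])[0]


def feature_table(
    env: EnvelopeRecording,
    cfg: WindowConfig,
    timeline=None,
    gesture: int | None = None,
    trial_id: str = "",
) -> pd.DataFrame:
    """Vectorized window features for one trial as a tidy table.

    Columns: trial_id, start_ms, phase, label, then the 3C feature columns in
    the contract order.
    """
    t = window_samples(cfg.window_ms, env.fs)
    starts = window_starts(env.n_samples, env.fs, cfg)
    cols = feature_names(env.channel_names)
    if starts.size == 0:
        warnings.warn("trial shorter than one window; empty feature table", stacklevel=2)
        return pd.DataFrame(columns=["trial_id", "start_ms", "phase", "label", *cols])
    idx = starts[:, None] + np.arange(t)[None, :]
    blocks = np.transpose(env.samples[:, idx], (1, 0, 2))  # (n, C, T)
    feats = _features_from_blocks(blocks)
    start_ms = np.arange(starts.size) * cfg.step_ms
    if timeline is not None:
        phases = [timeline.phase_at(s + cfg.window_ms / 2.0) for s in start_ms]
        labels = [_label_for(p, gesture) for p in phases]
    else:
        phases = [None] * starts.size
        labels = [None] * starts.size
    df = pd.DataFrame(feats, columns=cols)
    df.insert(0, "label", labels)
    df.insert(0, "phase", phases)
    df.insert(0, "start_ms", start_ms)
    df.insert(0, "trial_id", trial_id)
    return df
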