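"""Shared containers for multichannel surface-EMG processing.

A trial is a short multichannel recording of a reach-to-grasp movement split
into four ordered phases (reaching, grasping, returning, resting).  Gesture
labels use ``l = 0`` for the open-palm/rest gesture and ``l = 1..13`` for the
grasp gestures, 14 classes in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_NAMES: tuple[str, str, str, str] = ("reaching", "grasping", "returning", "resting")
MOTIONAL_PHASES: tuple[str, str, str] = ("reaching", "grasping", "returning")
REST_LABEL: int = 0
N_CLASSES: int = 14

#: Muscles covered by the 12-channel montage, hand to upper arm.
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "FDI", "APB", "FDM", "EI", "EDC", "FDS",
    "BRD", "ECR", "ECU", "FCU", "BIC", "TRI",
)


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""


@dataclass
class EmgRecording:
    """Multichannel EMG signal, one row per muscle channel.

    Parameters
    ----------
    samples : ndarray, shape (C, N)
        Signal values in arbitrary amplitude units.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Muscle labels, one per row of ``samples``.
    meta : dict
        Free-form provenance (subject / session / object / trial ids).
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("recording must have at least one channel and one sample")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0


@dataclass
class EnvelopeRecording(EmgRecording):
    """Non-negative EMG envelope; ``normalized`` means fraction-of-MVC units."""

    normalized: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.samples < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class MvcProfile:
    """Per-muscle maximum envelope value from the MVC test, used as divisor."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("MVC profile is empty")
        bad = [c for c, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive MVC maxima for channels {bad}")

    def for_channels(self, channel_names: tuple[str, ...]) -> np.ndarray:
        missing = [c for c in channel_names if c not in self.values]
        if missing:
            raise ValueError(f"channels missing from MVC profile: {missing}")
        return np.array([self.values[c] for c in channel_names], dtype=float)


@dataclass(frozen=True)
class PhaseTimeline:
    """Ground-truth phase boundaries of one 4-s trial.

    ``breakpoints_ms`` are the three ordered instants separating reaching,
    grasping, returning and resting; the trial starts in the reaching phase.
    """

    trial_length_ms: float
    breakpoints_ms: tuple[float, float, float]
    phase_names: tuple[str, ...] = PHASE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints_ms", tuple(float(b) for b in self.breakpoints_ms))
        if len(self.breakpoints_ms) != 3:
            raise ValueError("a trial timeline has exactly 3 breakpoints")
        b1, b2, b3 = self.breakpoints_ms
        if not (0 < b1 < b2 < b3 < self.trial_length_ms):
            raise ValueError(
                f"breakpoints {self.breakpoints_ms} must be strictly ordered within "
                f"(0, {self.trial_length_ms})"
            )

    @property
    def grasp_onset_ms(self) -> float:
        return self.breakpoints_ms[0]

    def phase_at(self, t_ms: float) -> str:
        """Phase containing time ``t_ms``; times < 0 count as (preceding) rest."""
        if t_ms < 0:
            return "resting"
        for b, name in zip(self.breakpoints_ms, self.phase_names):
            if t_ms < b:
                return name
        return self.phase_names[3]

    def phase_durations_ms(self) -> tuple[float, float, float, float]:
        b1, b2, b3 = self.breakpoints_ms
        return (b1, b2 - b1, b3 - b2, self.trial_length_ms - b3)

    def breakpoint_samples(self, fs: float) -> np.ndarray:
        return np.array([int(round(b * fs / 1000.0)) for b in self.breakpoints_ms])
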