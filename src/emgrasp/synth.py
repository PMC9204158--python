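"""Protocol-faithful synthetic surface-EMG sessions with ground truth.

The generator emulates the reach-to-grasp collection protocol: sessions of
13 grasp gestures x 4 objects, 6 four-second trials per object, 12 channels
sampled at 1562.5 Hz, plus a 3-s maximum-voluntary-contraction (MVC) burst
per muscle.  Each channel of a trial is a band-limited zero-mean Gaussian
carrier amplitude-modulated by a piecewise phase envelope: muscle tone at
rest, a gesture-specific activation pattern during grasping, and convex
blends of the two during reaching and returning (the reaching blend realizes
hand pre-shaping, i.e. gesture information available before the grasp).
Phase boundaries are smoothed with raised-cosine ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .datatypes import (
    DEFAULT_CHANNEL_NAMES,
    ConfigurationError,
    EmgRecording,
    PhaseTimeline,
)

__all__ = [
    "SyntheticProtocolConfig",
    "ActivationProfile",
    "SyntheticTrial",
    "SyntheticSession",
    "sample_trial_timeline",
    "synth_trial",
    "synth_mvc",
    "generate_session",
    "session_plan",
]


@dataclass(frozen=True)
class SyntheticProtocolConfig:
    """Counts, rates and signal-model knobs for one synthetic session."""

    n_channels: int = 12
    fs: float = 1562.5
    n_gestures: int = 13
    objects_per_gesture: int = 4
    trials_per_object: int = 6
    trial_length_ms: float = 4000.0
    min_phase_ms: float = 300.0
    mvc_duration_s: float = 3.0
    carrier_band: tuple[float, float] = (20.0, 450.0)
    carrier_order: int = 4
    noise_floor: float = 0.02
    rest_level: float = 0.05
    reach_blend: float = 0.6
    return_blend: float = 0.5
    ramp_ms: float = 50.0
    mvc_headroom: float = 1.5
    pattern_seed: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_channels, self.n_gestures,
            self.objects_per_gesture, self.trials_per_object,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all protocol counts must be >= 1")
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ConfigurationError("carrier band must satisfy 0 < low < high")
        if not self.fs > 2 * hi:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the carrier band edge {hi}"
            )
        if self.min_phase_ms * 4 > self.trial_length_ms:
            raise ConfigurationError("four minimum-length phases exceed the trial length")
        if not (0 <= self.reach_blend <= 1 and 0 <= self.return_blend <= 1):
            raise ConfigurationError("phase blends must lie in [0, 1]")

    @property
    def n_objects(self) -> int:
        return self.n_gestures * self.objects_per_gesture

    @property
    def n_trials(self) -> int:
        return self.n_objects * self.trials_per_object

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels <= len(DEFAULT_CHANNEL_NAMES):
            return DEFAULT_CHANNEL_NAMES[: self.n_channels]
        extra = tuple(f"CH{i}" for i in range(len(DEFAULT_CHANNEL_NAMES), self.n_channels))
        return DEFAULT_CHANNEL_NAMES + extra


@dataclass(frozen=True)
class ActivationProfile:
    """Per (gesture, phase, channel) envelope amplitudes, unitless MVC-like scale.

    ``grasp`` holds one amplitude row per gesture (row g-1 for gesture g);
    ``rest`` is the baseline muscle tone.  Reaching and returning amplitudes
    are convex blends ``rest + blend * (grasp - rest)``, so grasping never
    falls below reaching on any channel.
    """

    grasp: np.ndarray
    rest: np.ndarray
    reach_blend: float = 0.6
    return_blend: float = 0.5
    ramp_ms: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grasp", np.asarray(self.grasp, dtype=float))
        object.__setattr__(self, "rest", np.asarray(self.rest, dtype=float))
        if self.grasp.ndim != 2 or self.rest.ndim != 1:
            raise ValueError("grasp must be (G, C), rest must be (C,)")
        if self.grasp.shape[1] != self.rest.shape[0]:
            raise ValueError("grasp and rest channel counts differ")
        if np.any(self.grasp < 0) or np.any(self.rest < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_gestures(self) -> int:
        return self.grasp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.grasp.shape[1]

    def phase_amplitudes(self, gesture_id: int) -> np.ndarray:
        """Amplitude per (phase, channel): rows reaching/grasping/returning/resting."""
        if not 1 <= gesture_id <= self.n_gestures:
            raise ValueError(f"gesture_id {gesture_id} outside 1..{self.n_gestures}")
        g = self.grasp[gesture_id - 1]
        reach = self.rest + self.reach_blend * (g - self.rest)
        ret = self.rest + self.return_blend * (g - self.rest)
        return np.stack([reach, g, ret, self.rest])

    def max_task_amplitude(self) -> np.ndarray:
        """Largest amplitude any task phase can reach, per channel."""
        return np.maximum(self.grasp.max(axis=0), self.rest)

    @classmethod
    def from_config(cls, config: SyntheticProtocolConfig) -> "ActivationProfile":
        """Deterministic gesture-specific patterns, separable by construction.

        Each gesture draws channel amplitudes uniformly and is given one
        dominant channel so that patterns of distinct gestures differ.
        """
        rng = np.random.default_rng(config.pattern_seed)
        grasp = rng.uniform(0.1, 0.9, size=(config.n_gestures, config.n_channels))
        for g in range(config.n_gestures):
            grasp[g, g % config.n_channels] = 1.0
        rest = np.full(config.n_channels, config.rest_level)
        return cls(
            grasp=grasp,
            rest=rest,
            reach_blend=config.reach_blend,
            return_blend=config.return_blend,
            ramp_ms=config.ramp_ms,
        )


@dataclass
class SyntheticTrial:
    """One generated trial with its ground truth."""

    recording: EmgRecording
    timeline: PhaseTimeline
    gesture: int
    object_id: int
    trial_index: int

    @property
    def trial_id(self) -> str:
        return f"o{self.object_id:02d}t{self.trial_index}"


@dataclass
class SyntheticSession:
    """All trials of a session plus MVC recordings and a ground-truth manifest."""

    config: SyntheticProtocolConfig
    profile: ActivationProfile
    trials: list[SyntheticTrial]
    mvc: dict[str, EmgRecording]
    manifest: dict = field(default_factory=dict)

    def trials_by_object(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for t in self.trials:
            out.setdefault(t.object_id, []).append(t.trial_id)
        return out

    def trial_map(self) -> dict[str, SyntheticTrial]:
        return {t.trial_id: t for t in self.trials}


def sample_trial_timeline(
    config: SyntheticProtocolConfig, gesture_id: int, rng: np.random.Generator
) -> PhaseTimeline:
    """Draw breakpoints uniformly over the feasible region.

    Subjects paced each phase freely inside the 4-s trial, so the three
    breakpoints are uniform over all placements that leave every phase at
    least ``min_phase_ms`` long (the classic order-statistics construction:
    sorted uniforms on the slack, shifted by the minimum gaps).  The
    ``gesture_id`` is validated but does not influence pacing.
    """
    if not 1 <= gesture_id <= config.n_gestures:
        raise ValueError(f"gesture_id {gesture_id} outside 1..{config.n_gestures}")
    slack = config.trial_length_ms - 4 * config.min_phase_ms
    if slack < 0:
        raise ConfigurationError("minimum phase durations exceed the trial length")
    u = np.sort(rng.uniform(0.0, slack, size=3))
    b = u + config.min_phase_ms * np.arange(1, 4)
    return PhaseTimeline(config.trial_length_ms, tuple(b))


def _band_limited_carrier(
    n_samples: int, n_channels: int, config: SyntheticProtocolConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance zero-mean Gaussian noise band-limited to the carrier band."""
    sos = signal.butter(
        config.carrier_order, config.carrier_band, btype="bandpass",
        fs=config.fs, output="sos",
    )
    white = rng.standard_normal((n_channels, n_samples))
    carrier = signal.sosfiltfilt(sos, white, axis=1)
    std = carrier.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return carrier / std


def _phase_envelope(
    timeline: PhaseTimeline, amplitudes: np.ndarray, fs: float, ramp_ms: float
) -> np.ndarray:
    """(C, N) piecewise envelope with raised-cosine crossfades at boundaries."""
    n = int(round(timeline.trial_length_ms * fs / 1000.0))
    bounds = [0, *timeline.breakpoint_samples(fs).tolist(), n]
    env = np.empty((amplitudes.shape[1], n))
    for k in range(4):
        env[:, bounds[k]:bounds[k + 1]] = amplitudes[k][:, None]
    r = int(round(ramp_ms * fs / 1000.0))
    if r >= 2:
        w = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / (r - 1)))
        for k in range(1, 4):
            b = bounds[k]
            lo = max(0, b - r // 2)
            hi = min(n, lo + r)
            a_prev, a_next = amplitudes[k - 1][:, None], amplitudes[k][:, None]
            env[:, lo:hi] = a_prev + (a_next - a_prev) * w[: hi - lo][None, :]
    return env


def synth_trial(
    timeline: PhaseTimeline,
    gesture_id: int,
    profile: ActivationProfile,
    config: SyntheticProtocolConfig,
    rng: np.random.Generator,
    object_id: int = 0,
    trial_index: int = 0,
) -> SyntheticTrial:
    """Realize one trial: carrier x phase envelope + independent noise floor."""
    amps = profile.phase_amplitudes(gesture_id)
    env = _phase_envelope(timeline, amps, config.fs, profile.ramp_ms)
    n = env.shape[1]
    carrier = _band_limited_carrier(n, config.n_channels, config, rng)
    noise = _band_limited_carrier(n, config.n_channels, config, rng)
    samples = carrier * env + config.noise_floor * noise
    rec = EmgRecording(
        samples=samples,
        fs=config.fs,
        channel_names=config.channel_names,
        meta={"gesture": gesture_id, "object": object_id, "trial": trial_index},
    )
    return SyntheticTrial(rec, timeline, gesture_id, object_id, trial_index)


def synth_mvc(
    config: SyntheticProtocolConfig,
    profile: ActivationProfile,
    rng: np.random.Generator,
) -> dict[str, EmgRecording]:
    """One 3-s isometric burst per muscle, exceeding its maximum task amplitude.

    The target channel carries ``mvc_headroom`` times its largest task
    activation; the remaining channels sit at resting tone.
    """
    n = int(round(config.mvc_duration_s * config.fs))
    max_task = profile.max_task_amplitude()
    out: dict[str, EmgRecording] = {}
    for c, name in enumerate(config.channel_names):
        amps = profile.rest.copy()
        amps[c] = config.mvc_headroom * max_task[c]
        carrier = _band_limited_carrier(n, config.n_channels, config, rng)
        noise = _band_limited_carrier(n, config.n_channels, config, rng)
        samples = carrier * amps[:, None] + config.noise_floor * noise
        out[name] = EmgRecording(
            samples=samples,
            fs=config.fs,
            channel_names=config.channel_names,
            meta={"mvc_target": name},
        )
    return out


def session_plan(config: SyntheticProtocolConfig) -> list[dict]:
    """Enumerate (object, gesture, trial) rows of a session without signals."""
    plan = []
    for obj in range(config.n_objects):
        gesture = obj // config.objects_per_gesture + 1
        for k in range(config.trials_per_object):
            plan.append({
                "trial_id": f"o{obj:02d}t{k}",
                "object_id": obj,
                "gesture": gesture,
                "trial_index": k,
            })
    return plan


def generate_session(
    config: SyntheticProtocolConfig,
    profile: ActivationProfile | None = None,
) -> SyntheticSession:
    """Generate every trial and MVC burst of a session, with manifest.

    Reproducible: per-trial random streams are spawned deterministically from
    ``config.seed``, so identical configs yield bit-identical sessions.
    """
    if profile is None:
        profile = ActivationProfile.from_config(config)
    plan = session_plan(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(plan) + 1)
    trials: list[SyntheticTrial] = []
    for row, child in zip(plan, children[:-1]):
        rng = np.random.default_rng(child)
        timeline = sample_trial_timeline(config, row["gesture"], rng)
        trials.append(
            synth_trial(
                timeline, row["gesture"], profile, config, rng,
                object_id=row["object_id"], trial_index=row["trial_index"],
            )
        )
    mvc = synth_mvc(config, profile, np.random.default_rng(children[-1]))
    manifest = {
        "seed": config.seed,
        "n_objects": config.n_objects,
        "n_trials": config.n_trials,
        "fs": config.fs,
        "channel_names": list(config.channel_names),
        "trials": [
            {
                **row,
                "breakpoints_ms": list(t.timeline.breakpoints_ms),
            }
            for row, t in zip(plan, trials)
        ],
    }
    return SyntheticSession(config, profile, trials, mvc, manifest)
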