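"""Band-pass filtering, envelope extraction and MVC normalization.

Task and MVC recordings pass through the same chain: a fourth-order 40-500 Hz
Butterworth band-pass, full-wave rectification, and a second-order low-pass
(6 Hz) to form the linear envelope.  Each task channel is then divided by the
maximum of that muscle's MVC envelope so amplitudes become fractions of
maximum voluntary contraction, putting weak hand muscles and strong upper-arm
muscles on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy import signal

from .datatypes import ConfigurationError, EmgRecording, EnvelopeRecording, MvcProfile

__all__ = [
    "PreprocessSettings",
    "bandpass",
    "envelope",
    "mvc_profile",
    "normalize",
    "preprocess_trial",
]

#: forward-backward filtering leaves transients near the edges; flagged in meta
EDGE_MS = 100.0


@dataclass(frozen=True)
class PreprocessSettings:
    band_low_hz: float = 40.0
    band_high_hz: float = 500.0
    band_order: int = 4
    env_cutoff_hz: float = 6.0
    env_order: int = 2
    env_method: str = "rectify_lowpass"  # or "hilbert"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("band edges must satisfy 0 < low < high")
        if self.env_method not in ("rectify_lowpass", "hilbert"):
            raise ConfigurationError(f"unknown envelope method {self.env_method!r}")


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=1)
    return signal.sosfilt(sos, x, axis=1)


def bandpass(
    rec: EmgRecording,
    low_hz: float = 40.0,
    high_hz: float = 500.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EmgRecording:
    """Butterworth band-pass per channel (zero-phase by default).

    A high edge at or above Nyquist is clipped to 0.99 x Nyquist with a
    warning; at the native 1562.5 Hz rate the 500 Hz edge needs no clipping.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ConfigurationError("band edges must satisfy 0 < low < high")
    if high_hz >= nyq:
        clipped = 0.99 * nyq
        if low_hz >= clipped:
            raise ConfigurationError(
                f"band ({low_hz}, {high_hz}) lies outside Nyquist {nyq} even after clipping"
            )
        warnings.warn(
            f"band-pass high edge {high_hz} Hz clipped to {clipped:.1f} Hz "
            f"(Nyquist {nyq} Hz)",
            stacklevel=2,
        )
        high_hz = clipped
    if rec.n_samples <= 3 * (2 * order + 1):
        raise ValueError(
            f"signal of {rec.n_samples} samples too short for order-{order} "
            "forward-backward filtering"
        )
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass", fs=rec.fs, output="sos")
    out = _apply_sos(sos, rec.samples, zero_phase)
    meta = {**rec.meta, "bandpass_hz": (low_hz, high_hz), "edge_ms": EDGE_MS}
    return EmgRecording(out, rec.fs, rec.channel_names, meta)


def envelope(
    rec: EmgRecording,
    lp_cutoff_hz: float = 6.0,
    lp_order: int = 2,
    method: str = "rectify_lowpass",
    zero_phase: bool = True,
) -> EnvelopeRecording:
    """Linear envelope: full-wave rectification + zero-phase low-pass.

    ``method="hilbert"`` uses the analytic-signal magnitude (low-passed with
    the same filter) instead of rectification.
    """
    if method == "rectify_lowpass":
        rect = np.abs(rec.samples)
    elif method == "hilbert":
        rect = np.abs(signal.hilbert(rec.samples, axis=1))
    else:
        raise ConfigurationError(f"unknown envelope method {method!r}")
    sos = signal.butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=rec.fs, output="sos")
    env = _apply_sos(sos, rect, zero_phase)
    np.clip(env, 0.0, None, out=env)
    meta = {**rec.meta, "envelope": method, "env_cutoff_hz": lp_cutoff_hz, "edge_ms": EDGE_MS}
    return EnvelopeRecording(env, rec.fs, rec.channel_names, meta, normalized=False)


def mvc_profile(mvc_envelopes: Iterable[EnvelopeRecording]) -> MvcProfile:
    """Per-channel maximum over all MVC envelope samples.

    Every channel present in any input contributes; the maximum is taken
    across recordings, so concatenation order is irrelevant.
    """
    maxima: dict[str, float] = {}
    for env in mvc_envelopes:
        per_ch = env.samples.max(axis=1)
        for name, m in zip(env.channel_names, per_ch):
            maxima[name] = max(maxima.get(name, 0.0), float(m))
    if not maxima:
        raise ValueError("no MVC recordings supplied")
    return MvcProfile(maxima)


def normalize(env: EnvelopeRecording, mvc: MvcProfile) -> EnvelopeRecording:
    """Divide each channel by its MVC envelope maximum."""
    divisors = mvc.for_channels(env.channel_names)
    out = env.samples / divisors[:, None]
    return EnvelopeRecording(
        out, env.fs, env.channel_names, {**env.meta, "normalized_by": "mvc"},
        normalized=True,
    )


def preprocess_trial(rec: EmgRecording, settings: PreprocessSettings) -> EnvelopeRecording:
    """Band-pass then envelope with one settings object (used for task and MVC)."""
    filtered = bandpass(
        rec, settings.band_low_hz, settings.band_high_hz,
        settings.band_order, settings.zero_phase,
    )
    return envelope(
        filtered, settings.env_cutoff_hz, settings.env_order,
        settings.env_method, settings.zero_phase,
    )
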