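"""Greedy Gaussian segmentation (GGS) of trials into movement phases.

A trial's multichannel series is partitioned into K+1 contiguous segments,
each modeled as an i.i.d. multivariate Gaussian with its own mean and
covariance.  The score of a segment [i, j) is the profiled log-likelihood up
to partition-independent constants,

    score(i, j) = -(n / 2) * log det(S + reg * I),   n = j - i,

where S is the population covariance about the segment mean and
``reg = lam * tr(S) / d + abs_floor`` is trace-scaled diagonal loading (the
absolute floor keeps constant segments finite).  Breakpoints are inserted
greedily one at a time at the position maximizing the total score, and after
each insertion cyclic adjustment sweeps re-optimize every breakpoint between
its neighbors until convergence.  An exact dynamic-programming solver over
the same objective serves as a brute-force oracle on small instances.

With K = 3 the four segments map, in temporal order, to the reaching,
grasping, returning and resting phases of a reach-to-grasp trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import comb

import numpy as np
from scipy import signal

from .datatypes import ConfigurationError, EnvelopeRecording, PHASE_NAMES

__all__ = [
    "GgsConfig",
    "SegmentedTrial",
    "segment_score",
    "ggs_fit",
    "exhaustive_fit",
    "assign_phases",
    "annotate_gesture",
    "segment_envelope",
]

ABS_FLOOR = 1e-12


@dataclass(frozen=True)
class GgsConfig:
    """Knobs of the segmentation stage.

    ``min_segment_ms`` guards against implausibly short phases;
    ``decimate_to_hz`` is the working rate for envelopes (they are slow
    signals, so 100 Hz retains the structure at ~1/16 the cost).  ``cov_reg``
    needs to be substantial for 12-channel envelopes: at 100 Hz a minimum
    segment holds only ~10 heavily autocorrelated samples, so unshrunk
    covariances are rank-deficient and near-singular segments would dominate
    the log-det objective; diagonal loading at 0.3 of the average channel
    variance suppresses that failure mode.
    """

    n_breakpoints: int = 3
    cov_reg: float = 0.3
    min_segment_ms: float = 100.0
    min_segment_samples: int | None = None
    decimate_to_hz: float = 100.0
    max_sweeps: int = 20
    on: str = "envelope"  # or "raw": segment the band-passed signal instead

    def __post_init__(self) -> None:
        if self.n_breakpoints < 0:
            raise ConfigurationError("n_breakpoints must be >= 0")
        if not self.cov_reg > 0:
            raise ConfigurationError("cov_reg must be positive")
        if self.max_sweeps < 1:
            raise ConfigurationError("max_sweeps must be >= 1")
        if self.min_segment_samples is not None and self.min_segment_samples < 2:
            raise ConfigurationError("min_segment_samples must be >= 2")

    def resolve_min_segment(self, fs: float | None) -> int:
        if self.min_segment_samples is not None:
            return self.min_segment_samples
        if fs is None:
            raise ConfigurationError(
                "min_segment_ms needs a sampling rate; pass fs or set min_segment_samples"
            )
        return max(2, int(round(self.min_segment_ms * fs / 1000.0)))


@dataclass
class SegmentedTrial:
    """K ordered breakpoints of one trial, at the segmentation rate and mapped back.

    Segments are half-open index intervals [start, end) at the segmentation
    rate; ``breakpoints_orig`` / ``breakpoints_ms`` give the same instants at
    the original rate and in milliseconds.
    """

    breakpoints: np.ndarray
    n_samples: int
    fs_seg: float
    breakpoints_orig: np.ndarray
    n_samples_orig: int
    fs_orig: float
    objective: float
    objective_history: list[float] = field(default_factory=list)
    phase_names: tuple[str, ...] | None = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=int)
        self.breakpoints_orig = np.asarray(self.breakpoints_orig, dtype=int)
        b = self.breakpoints
        if b.size and not (np.all(np.diff(b) > 0) and 0 < b[0] and b[-1] < self.n_samples):
            raise ValueError("breakpoints must be strictly ordered inside (0, n_samples)")

    @property
    def n_breakpoints(self) -> int:
        return int(self.breakpoints.size)

    @property
    def breakpoints_ms(self) -> np.ndarray:
        return self.breakpoints / self.fs_seg * 1000.0

    @property
    def segments(self) -> list[tuple[int, int]]:
        edges = [0, *self.breakpoints.tolist(), self.n_samples]
        return [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]

    @property
    def grasp_onset_ms(self) -> float:
        if self.n_breakpoints < 1:
            raise ValueError("no breakpoints")
        return float(self.breakpoints_ms[0])

    def phase_at(self, t_ms: float) -> str:
        """Phase containing ``t_ms``; requires phase names (K = 3)."""
        if self.phase_names is None:
            raise ValueError("phases not assigned; call assign_phases first")
        if t_ms < 0:
            return "resting"
        for b, name in zip(self.breakpoints_ms, self.phase_names):
            if t_ms < b:
                return name
        return self.phase_names[-1]

    def to_dict(self) -> dict:
        return {
            "breakpoints": self.breakpoints.tolist(),
            "n_samples": self.n_samples,
            "fs_seg": self.fs_seg,
            "breakpoints_orig": self.breakpoints_orig.tolist(),
            "n_samples_orig": self.n_samples_orig,
            "fs_orig": self.fs_orig,
            "objective": self.objective,
            "objective_history": list(self.objective_history),
            "phase_names": list(self.phase_names) if self.phase_names else None,
            "trial_id": self.trial_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentedTrial":
        d = dict(d)
        if d.get("phase_names"):
            d["phase_names"] = tuple(d["phase_names"])
        return cls(**d)


class _SegmentStats:
    """Prefix sums enabling O(d^2) covariance of any interval, batched."""

    def __init__(self, data: np.ndarray, lam: float, abs_floor: float = ABS_FLOOR):
        x = np.asarray(data, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.n, self.d = x.shape
        self.lam = lam
        self.abs_floor = abs_floor
        self.c1 = np.zeros((self.n + 1, self.d))
        np.cumsum(x, axis=0, out=self.c1[1:])
        outer = x[:, :, None] * x[:, None, :]
        self.c2 = np.zeros((self.n + 1, self.d, self.d))
        np.cumsum(outer, axis=0, out=self.c2[1:])
        self._eye = np.eye(self.d)

    def score(self, i, j) -> np.ndarray | float:
        """Regularized Gaussian log-likelihood score of [i, j), broadcastable."""
        i = np.asarray(i, dtype=int)
        j = np.asarray(j, dtype=int)
        n = (j - i).astype(float)
        if np.any(n < 1):
            raise ValueError("degenerate interval: j must exceed i")
        mean = (self.c1[j] - self.c1[i]) / n[..., None]
        cov = (self.c2[j] - self.c2[i]) / n[..., None, None] \
            - mean[..., :, None] * mean[..., None, :]
        cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
        tr = np.trace(cov, axis1=-2, axis2=-1)
        reg = self.lam * tr / self.d + self.abs_floor
        _, logdet = np.linalg.slogdet(cov + reg[..., None, None] * self._eye)
        out = -(n / 2.0) * logdet
        return float(out) if out.ndim == 0 else out

    def total(self, breakpoints: list[int]) -> float:
        edges = [0, *breakpoints, self.n]
        return float(sum(self.score(edges[k], edges[k + 1]) for k in range(len(edges) - 1)))


def segment_score(
    data: np.ndarray, i: int, j: int, lam: float, abs_floor: float = ABS_FLOOR
) -> float:
    """Score of segment [i, j) of ``data`` (time-major, shape (N, d))."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not 0 <= i < j <= x.shape[0]:
        raise ValueError(f"invalid interval [{i}, {j}) for {x.shape[0]} samples")
    return float(_SegmentStats(x[i:j], lam, abs_floor).score(0, j - i))


def _best_split(stats: _SegmentStats, a: int, b: int, m: int) -> tuple[int, float] | None:
    """Best single split of [a, b); returns (t, combined score) or None if infeasible.

    Ties are broken toward the earliest index (argmax returns the first max).
    """
    lo, hi = a + m, b - m
    if lo > hi:
        return None
    cand = np.arange(lo, hi + 1)
    sc = stats.score(np.full_like(cand, a), cand) + stats.score(cand, np.full_like(cand, b))
    k = int(np.argmax(sc))
    return int(cand[k]), float(sc[k])


def _pair_scan(
    stats: _SegmentStats,
    a: int,
    b: int,
    m: int,
    stride: int,
    t1_range: tuple[int, int] | None = None,
    t2_range: tuple[int, int] | None = None,
) -> tuple[int, int, float] | None:
    """Best (t1, t2) pair on a strided grid inside [a, b); earliest-pair ties."""
    lo1 = a + m if t1_range is None else max(a + m, t1_range[0])
    hi1 = b - 2 * m if t1_range is None else min(b - 2 * m, t1_range[1])
    best: tuple[int, int, float] | None = None
    for t1 in range(lo1, hi1 + 1, stride):
        lo2 = t1 + m if t2_range is None else max(t1 + m, t2_range[0])
        hi2 = b - m if t2_range is None else min(b - m, t2_range[1])
        if lo2 > hi2:
            continue
        t2 = np.arange(lo2, hi2 + 1, stride)
        sc = stats.score(a, t1) + stats.score(np.full_like(t2, t1), t2) \
            + stats.score(t2, np.full_like(t2, b))
        k = int(np.argmax(sc))
        if best is None or sc[k] > best[2]:
            best = (t1, int(t2[k]), float(sc[k]))
    return best


def _best_double_split(
    stats: _SegmentStats, a: int, b: int, m: int
) -> tuple[int, int, float] | None:
    """Best joint placement of two breakpoints inside [a, b); None if infeasible.

    Small spans are scanned exhaustively; larger spans use a coarse grid
    followed by an exact local refinement around the coarse optimum.
    """
    if b - a < 3 * m:
        return None
    stride = max(1, (b - a) // 128)
    best = _pair_scan(stats, a, b, m, stride)
    if best is not None and stride > 1:
        t1c, t2c, _ = best
        best = _pair_scan(
            stats, a, b, m, 1,
            t1_range=(t1c - stride, t1c + stride),
            t2_range=(t2c - stride, t2c + stride),
        )
    return best


def ggs_fit(
    data: np.ndarray,
    config: GgsConfig,
    fs: float | None = None,
    trial_id: str = "",
) -> SegmentedTrial:
    """Greedy breakpoint insertion with cyclic adjustment sweeps.

    Each of the K insertions places a new breakpoint where it most increases
    the total score; the following sweeps re-optimize every breakpoint within
    the interval bounded by its neighbors until no breakpoint moves (or
    ``max_sweeps`` is hit).  The recorded objective history is non-decreasing
    (sweeps only accept strict improvements; insertions cannot lower the
    profiled likelihood).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    k_target = config.n_breakpoints
    m = config.resolve_min_segment(fs)
    if n < (k_target + 1) * m:
        raise ValueError(
            f"{n} samples cannot hold {k_target + 1} segments of >= {m} samples"
        )
    stats = _SegmentStats(x, config.cov_reg)
    bps: list[int] = []
    history = [stats.total(bps)]
    for _ in range(k_target):
        best: tuple[float, int, int] | None = None  # (score gain, split, insert pos)
        edges = [0, *bps, n]
        for s in range(len(edges) - 1):
            a, b = edges[s], edges[s + 1]
            found = _best_split(stats, a, b, m)
            if found is None:
                continue
            t, sc = found
            gain = sc - stats.score(a, b)
            if best is None or gain > best[0]:
                best = (gain, t, s)
        if best is None:
            raise ValueError("no feasible breakpoint insertion under the minimum-segment rule")
        bps.insert(best[2], best[1])
        # cyclic re-adjustment of every breakpoint between its neighbors
        for _sweep in range(config.max_sweeps):
            moved = False
            for idx in range(len(bps)):
                a = bps[idx - 1] if idx > 0 else 0
                b = bps[idx + 1] if idx + 1 < len(bps) else n
                found = _best_split(stats, a, b, m)
                if found is None:
                    continue
                t, sc = found
                cur = stats.score(a, bps[idx]) + stats.score(bps[idx], b)
                if t != bps[idx] and sc > cur + 1e-12:
                    bps[idx] = t
                    moved = True
            if not moved:
                break
        history.append(stats.total(bps))
    # global re-adjustment: local sweeps cannot carry a breakpoint past its
    # neighbor, so remove each one in turn and re-insert it at the globally
    # best position, until no such move improves the objective
    for _round in range(config.max_sweeps):
        improved = False
        for idx in range(len(bps)):
            rest = bps[:idx] + bps[idx + 1:]
            base = stats.total(rest)
            best_t, best_sc = None, stats.total(bps)
            edges = [0, *rest, n]
            for s in range(len(edges) - 1):
                found = _best_split(stats, edges[s], edges[s + 1], m)
                if found is None:
                    continue
                t, sc = found
                total = base - stats.score(edges[s], edges[s + 1]) + sc
                if total > best_sc + 1e-12:
                    best_t, best_sc = t, total
            if best_t is not None and best_t != bps[idx]:
                bps = sorted(rest + [best_t])
                improved = True
        # coupled moves: re-place each adjacent breakpoint pair jointly
        for idx in range(len(bps) - 1):
            rest = bps[:idx] + bps[idx + 2:]
            a = rest[idx - 1] if idx > 0 else 0
            b = rest[idx] if idx < len(rest) else n
            found = _best_double_split(stats, a, b, m)
            if found is None:
                continue
            t1, t2, sc = found
            cur = (
                stats.score(a, bps[idx])
                + stats.score(bps[idx], bps[idx + 1])
                + stats.score(bps[idx + 1], b)
            )
            if (t1, t2) != (bps[idx], bps[idx + 1]) and sc > cur + 1e-12:
                bps = sorted(rest + [t1, t2])
                improved = True
        if not improved:
            break
    history.append(stats.total(bps))
    fs_seg = fs if fs is not None else 1.0
    seg = SegmentedTrial(
        breakpoints=np.array(bps, dtype=int),
        n_samples=n,
        fs_seg=fs_seg,
        breakpoints_orig=np.array(bps, dtype=int),
        n_samples_orig=n,
        fs_orig=fs_seg,
        objective=history[-1],
        objective_history=history,
        trial_id=trial_id,
    )
    if k_target == 3:
        seg = assign_phases(seg)
    return seg


def exhaustive_fit(
    data: np.ndarray,
    n_breakpoints: int,
    lam: float,
    min_segment: int,
) -> tuple[np.ndarray, float]:
    """Globally optimal breakpoints by exact dynamic programming (test oracle).

    Refuses instances whose number of candidate partitions exceeds 1e6.
    Ties are broken toward the earliest predecessor at every DP cell.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    k = n_breakpoints
    m = max(2, int(min_segment))
    if n < (k + 1) * m:
        raise ValueError("instance infeasible under the minimum-segment rule")
    slack = n - (k + 1) * m
    if comb(slack + k, k) > 1_000_000:
        raise ValueError("instance too large for the exhaustive oracle")
    stats = _SegmentStats(x, lam)
    neg = -np.inf
    # f[q][j]: best score of covering [0, j) with q+1 segments
    f = np.full((k + 1, n + 1), neg)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    js = np.arange(m, n + 1)
    f[0, m:] = stats.score(np.zeros_like(js), js)
    for q in range(1, k + 1):
        lo_j = (q + 1) * m
        for j in range(lo_j, n + 1):
            is_ = np.arange(q * m, j - m + 1)
            vals = f[q - 1, is_] + stats.score(is_, np.full_like(is_, j))
            b = int(np.argmax(vals))
            f[q, j] = vals[b]
            arg[q, j] = is_[b]
    bps = []
    j = n
    for q in range(k, 0, -1):
        j = int(arg[q, j])
        bps.append(j)
    bps.reverse()
    return np.array(bps, dtype=int), float(f[k, n])


def assign_phases(seg: SegmentedTrial) -> SegmentedTrial:
    """Label the 4 segments reaching, grasping, returning, resting in order."""
    if seg.n_breakpoints != 3:
        raise ValueError(f"phase assignment needs exactly 3 breakpoints, got {seg.n_breakpoints}")
    return replace(seg, phase_names=PHASE_NAMES)


def annotate_gesture(seg: SegmentedTrial, gesture: int) -> np.ndarray:
    """Per-sample labels at the original rate: gesture on the three motional
    segments, 0 (open palm / rest) on the resting segment."""
    if not 1 <= gesture <= 13:
        raise ValueError(f"gesture label {gesture} outside 1..13")
    if seg.n_breakpoints != 3:
        raise ValueError("gesture annotation needs a 3-breakpoint segmentation")
    labels = np.full(seg.n_samples_orig, gesture, dtype=int)
    labels[seg.breakpoints_orig[2]:] = 0
    return labels


def segment_envelope(
    env: EnvelopeRecording, config: GgsConfig, trial_id: str = ""
) -> SegmentedTrial:
    """Decimate the envelope to the working rate, fit GGS, map breakpoints back.

    Decimation uses a polyphase anti-aliased resampler; breakpoints are mapped
    to original-rate sample indices by nearest-sample conversion.
    """
    ratio = Fraction(config.decimate_to_hz / env.fs).limit_denominator(10_000)
    if ratio >= 1:
        x = env.samples
        fs_seg = env.fs
    else:
        x = signal.resample_poly(env.samples, ratio.numerator, ratio.denominator, axis=1)
        fs_seg = env.fs * ratio.numerator / ratio.denominator
    seg = ggs_fit(x.T, config, fs=fs_seg, trial_id=trial_id)
    scale = env.fs / fs_seg
    b_orig = np.clip(
        np.round(seg.breakpoints * scale).astype(int), 1, env.n_samples - 1
    )
    return replace(
        seg,
        breakpoints_orig=b_orig,
        n_samples_orig=env.n_samples,
        fs_orig=env.fs,
    )
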