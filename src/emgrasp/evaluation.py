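"""Grasp-onset-aligned evaluation: probability curves, t_i, d_p, confusion.

Every validation trial is re-expressed on a time axis where 0 ms is the
start of its grasping phase (the first segmentation breakpoint), and 700 ms
of resting-phase signal from the end of the preceding trial is prepended so
the rest-to-reach transition is visible.  Per-window probability vectors are
averaged across trials on this aligned 40-ms grid, yielding

* ``p_grasp(t)``  — mean probability of each trial's own grasp gesture,
* ``p_rest(t)``   — mean probability of the open-palm/rest class,
* ``p_top(t)``    — mean probability of the *top competitor*, the strongest
  class that is neither rest nor the trial's gesture (taken per trial and
  per time point before averaging, so the competitor may change over time),

plus grasp/rest detection-accuracy curves.  Two scalar summaries follow:
``t_i`` — the earliest time at which p_grasp overtakes p_rest (negative
means before grasp onset), and ``d_p`` — the margin between the p_grasp peak
and the simultaneous top-competitor probability.  A row-normalized 14x14
confusion matrix over the pre-shaping window [t_a, 0] summarizes which
gestures are mistaken for which before the grasp closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MOTIONAL_PHASES, N_CLASSES, REST_LABEL

__all__ = [
    "AlignedTrial",
    "EvaluationCurves",
    "ConfusionSummary",
    "align",
    "average_curves",
    "accuracy_curves",
    "intersection_time",
    "probability_margin",
    "confusion",
]


@dataclass
class AlignedTrial:
    """Windowed predictions of one trial on the grasp-onset-relative grid."""

    times_ms: np.ndarray          # snapped to the window-step grid, ascending
    proba: np.ndarray             # (n, 14)
    phases: list[str]
    gesture: int
    prepended: np.ndarray         # bool mask: windows from the previous trial's rest
    has_prepend: bool
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.proba = np.asarray(self.proba, dtype=float)
        self.prepended = np.asarray(self.prepended, dtype=bool)
        n = self.times_ms.size
        if self.proba.shape != (n, N_CLASSES):
            raise ValueError(f"proba must be ({n}, {N_CLASSES})")
        if len(self.phases) != n or self.prepended.size != n:
            raise ValueError("phases/prepended length mismatch")
        if n > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("aligned times must be strictly increasing")

    def top_competitor(self) -> np.ndarray:
        """max_j p_j excluding rest and the trial's own gesture, per window."""
        mask = np.ones(N_CLASSES, dtype=bool)
        mask[REST_LABEL] = False
        mask[self.gesture] = False
        return self.proba[:, mask].max(axis=1)


def align(
    start_times_ms: np.ndarray,
    proba: np.ndarray,
    phases: Sequence[str],
    grasp_onset_ms: float,
    gesture: int,
    step_ms: float = 40.0,
    prepended: np.ndarray | None = None,
    has_prepend: bool = True,
    trial_id: str = "",
) -> AlignedTrial:
    """Shift window start times to the grasp-onset origin and snap to the grid.

    ``start_times_ms`` are trial-coordinate window starts (negative for
    windows from the prepended resting context).  Snapping rounds the common
    offset to the nearest grid step, so a window starting exactly at the
    breakpoint lands at 0 ms.
    """
    start_times_ms = np.asarray(start_times_ms, dtype=float)
    shift = round(grasp_onset_ms / step_ms) * step_ms
    times = start_times_ms - shift
    if prepended is None:
        prepended = np.zeros(start_times_ms.size, dtype=bool)
    return AlignedTrial(
        times_ms=times,
        proba=proba,
        phases=list(phases),
        gesture=gesture,
        prepended=prepended,
        has_prepend=has_prepend,
        trial_id=trial_id,
    )


@dataclass
class EvaluationCurves:
    """Trial-averaged probability and accuracy curves with support counts."""

    times_ms: np.ndarray
    p_grasp: np.ndarray
    p_rest: np.ndarray
    p_top: np.ndarray
    acc_grasp: np.ndarray
    acc_rest: np.ndarray
    support: np.ndarray        # trials contributing a window at each grid point
    support_grasp: np.ndarray  # trials whose phase at t is motional
    support_rest: np.ndarray   # trials whose phase at t is resting
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.times_ms,
            "p_grasp": self.p_grasp,
            "p_rest": self.p_rest,
            "p_top": self.p_top,
            "acc_grasp": self.acc_grasp,
            "acc_rest": self.acc_rest,
            "support": self.support,
            "support_grasp": self.support_grasp,
            "support_rest": self.support_rest,
        })


def average_curves(trials: Sequence[AlignedTrial]) -> EvaluationCurves:
    """Average probability/accuracy over trials at each aligned grid point.

    Each grid point averages only the trials whose aligned span covers it;
    support counts record how many did.  Accuracy curves are conditioned on
    the trial's phase at that point: grasp accuracy counts argmax == gesture
    among motional-phase trials, rest accuracy counts argmax == 0 among
    resting-phase trials (prepended rest context included).
    """
    if not trials:
        raise ValueError("no aligned trials to average")
    all_times = np.unique(np.concatenate([t.times_ms for t in trials]))
    n = all_times.size
    sums = {k: np.zeros(n) for k in ("p_grasp", "p_rest", "p_top", "acc_grasp", "acc_rest")}
    support = np.zeros(n, dtype=int)
    support_grasp = np.zeros(n, dtype=int)
    support_rest = np.zeros(n, dtype=int)
    for tr in trials:
        idx = np.searchsorted(all_times, tr.times_ms)
        support[idx] += 1
        sums["p_grasp"][idx] += tr.proba[:, tr.gesture]
        sums["p_rest"][idx] += tr.proba[:, REST_LABEL]
        sums["p_top"][idx] += tr.top_competitor()
        pred = np.argmax(tr.proba, axis=1)  # ties -> lowest class index
        motional = np.array([p in MOTIONAL_PHASES for p in tr.phases])
        resting = ~motional
        support_grasp[idx[motional]] += 1
        sums["acc_grasp"][idx[motional]] += (pred[motional] == tr.gesture)
        support_rest[idx[resting]] += 1
        sums["acc_rest"][idx[resting]] += (pred[resting] == REST_LABEL)

    def _div(s: np.ndarray, c: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        nz = c > 0
        out[nz] = s[nz] / c[nz]
        return out

    return EvaluationCurves(
        times_ms=all_times,
        p_grasp=_div(sums["p_grasp"], support),
        p_rest=_div(sums["p_rest"], support),
        p_top=_div(sums["p_top"], support),
        acc_grasp=_div(sums["acc_grasp"], support_grasp),
        acc_rest=_div(sums["acc_rest"], support_rest),
        support=support,
        support_grasp=support_grasp,
        support_rest=support_rest,
        n_trials=len(trials),
    )


def accuracy_curves(trials: Sequence[AlignedTrial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, grasp accuracy, rest accuracy) per aligned grid point."""
    c = average_curves(trials)
    return c.times_ms, c.acc_grasp, c.acc_rest


def _valid_mask(curves: EvaluationCurves, min_support_frac: float) -> np.ndarray:
    need = max(1, math.ceil(min_support_frac * curves.n_trials))
    return (
        (curves.support >= need)
        & np.isfinite(curves.p_grasp)
        & np.isfinite(curves.p_rest)
    )


def intersection_time(
    curves: EvaluationCurves,
    persistence: int = 3,
    min_support_frac: float = 0.2,
) -> float | None:
    """Earliest time where p_grasp overtakes p_rest and stays above.

    The crossing must persist for ``persistence`` consecutive supported grid
    points; the instant is refined by linear interpolation between the two
    bracketing points.  Grid points supported by fewer than
    ``min_support_frac`` of trials are ignored.  Returns None if the curves
    never cross.
    """
    vi = np.flatnonzero(_valid_mask(curves, min_support_frac))
    if vi.size == 0:
        return None
    g = curves.p_grasp[vi]
    r = curves.p_rest[vi]
    above = g >= r
    for q in range(vi.size - persistence + 1):
        if above[q:q + persistence].all():
            t1 = curves.times_ms[vi[q]]
            if q == 0:
                return float(t1)
            t0 = curves.times_ms[vi[q - 1]]
            d0 = g[q - 1] - r[q - 1]  # < 0
            d1 = g[q] - r[q]          # >= 0
            if d1 == d0:
                return float(t1)
            return float(t0 + (-d0) / (d1 - d0) * (t1 - t0))
    return None


def probability_margin(
    curves: EvaluationCurves, min_support_frac: float = 0.2
) -> float:
    """d_p: p_grasp at its peak minus the simultaneous top-competitor mean.

    The peak location breaks ties toward the earliest time.
    """
    vi = np.flatnonzero(_valid_mask(curves, min_support_frac) & np.isfinite(curves.p_top))
    if vi.size == 0:
        raise ValueError("no supported grid points for the probability margin")
    k = vi[int(np.argmax(curves.p_grasp[vi]))]
    return float(curves.p_grasp[k] - curves.p_top[k])


@dataclass
class ConfusionSummary:
    """Row-normalized 14x14 confusion over a stated aligned-time window."""

    matrix: np.ndarray
    counts: np.ndarray
    window_ms: tuple[float, float]
    mean_diagonal: float

    def populated_classes(self) -> np.ndarray:
        return np.flatnonzero(self.counts.sum(axis=1) > 0)


def confusion(
    trials: Sequence[AlignedTrial],
    window_ms: tuple[float, float] = (-700.0, 0.0),
) -> ConfusionSummary:
    """Confusion of argmax predictions over windows inside ``window_ms``.

    True class is the trial gesture; rows are normalized where populated and
    the mean diagonal is taken over populated rows only.
    """
    t_a, t_b = window_ms
    if not t_a < t_b:
        raise ValueError("confusion window must satisfy t_a < t_b")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for tr in trials:
        sel = (tr.times_ms >= t_a) & (tr.times_ms <= t_b)
        if not np.any(sel):
            continue
        pred = np.argmax(tr.proba[sel], axis=1)
        for p in pred:
            counts[tr.gesture, p] += 1
    row_sums = counts.sum(axis=1)
    if not np.any(row_sums):
        raise ValueError(f"no windows fall inside the confusion window {window_ms}")
    matrix = np.zeros_like(counts, dtype=float)
    pop = row_sums > 0
    matrix[pop] = counts[pop] / row_sums[pop, None]
    mean_diag = float(np.mean(np.diag(matrix)[pop]))
    return ConfusionSummary(
        matrix=matrix, counts=counts, window_ms=(float(t_a), float(t_b)),
        mean_diagonal=mean_diag,
    )
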