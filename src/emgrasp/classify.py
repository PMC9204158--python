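"""14-class gesture decoding with extremely randomized trees.

The decoder is an extra-trees ensemble of 50 trees over the 3C window
features.  Training follows the per-object 4/2 trial split (three folds, each
trial validated exactly once) and one of three phase-selection strategies:

* S1 — reaching + resting windows,
* S2 — grasping + resting windows,
* S3 — reaching + grasping + resting windows.

Returning-phase windows are never used for training under any strategy (by
then the grasp is already released); validation always covers whole trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .datatypes import N_CLASSES
from .windows import feature_names as _feature_names

__all__ = [
    "TrainingStrategy",
    "SplitPlan",
    "build_split",
    "select_training_windows",
    "train_model",
    "predict_proba",
    "GestureModel",
]


class TrainingStrategy(enum.Enum):
    """Which movement phases contribute training windows."""

    S1 = frozenset({"reaching", "resting"})
    S2 = frozenset({"grasping", "resting"})
    S3 = frozenset({"reaching", "grasping", "resting"})

    @property
    def phases(self) -> frozenset[str]:
        return self.value

    @classmethod
    def parse(cls, name: "str | TrainingStrategy") -> "TrainingStrategy":
        if isinstance(name, cls):
            return name
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(f"unknown strategy {name!r}; expected S1, S2 or S3") from None


@dataclass(frozen=True)
class SplitPlan:
    """Per-object partition of 6 trials into 3 disjoint validation pairs.

    Fold f validates pair f of every object and trains on the remaining 4
    trials, so every trial is validated exactly once across the 3 folds.
    """

    pairs: dict[int, tuple[tuple[str, str], tuple[str, str], tuple[str, str]]]
    seed: int

    @property
    def n_folds(self) -> int:
        return 3

    def fold(self, f: int) -> tuple[list[str], list[str]]:
        """(training trial ids, validation trial ids) of fold ``f``."""
        if not 0 <= f < 3:
            raise ValueError(f"fold {f} outside 0..2")
        train: list[str] = []
        val: list[str] = []
        for obj in sorted(self.pairs):
            for p, pair in enumerate(self.pairs[obj]):
                (val if p == f else train).extend(pair)
        return train, val


def build_split(trials_by_object: Mapping[int, Sequence[str]], seed: int) -> SplitPlan:
    """Seeded random pairing of each object's 6 trials into 3 folds."""
    rng = np.random.default_rng(seed)
    pairs: dict[int, tuple] = {}
    for obj in sorted(trials_by_object):
        ids = list(trials_by_object[obj])
        if len(ids) != 6:
            raise ValueError(f"object {obj} has {len(ids)} trials; the split needs exactly 6")
        order = rng.permutation(6)
        shuffled = [ids[i] for i in order]
        pairs[obj] = (
            (shuffled[0], shuffled[1]),
            (shuffled[2], shuffled[3]),
            (shuffled[4], shuffled[5]),
        )
    return SplitPlan(pairs=pairs, seed=seed)


def select_training_windows(
    features: pd.DataFrame, strategy: "TrainingStrategy | str"
) -> pd.DataFrame:
    """Keep only windows whose phase belongs to the strategy's phase set."""
    strategy = TrainingStrategy.parse(strategy)
    if "phase" not in features.columns:
        raise ValueError("feature table lacks phase tags")
    out = features[features["phase"].isin(strategy.phases)]
    if out.empty:
        raise ValueError(f"no windows left after {strategy.name} phase selection")
    return out


@dataclass
class GestureModel:
    """Fitted ensemble plus its feature-order contract and provenance."""

    estimator: ExtraTreesClassifier
    feature_names: list[str]
    strategy: TrainingStrategy | None
    seed: int
    n_classes: int = N_CLASSES

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_


def train_model(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | None = None,
    n_trees: int = 50,
    seed: int = 0,
    strategy: "TrainingStrategy | str | None" = None,
    channel_names: tuple[str, ...] | None = None,
) -> GestureModel:
    """Fit the 50-tree extra-trees ensemble on window features.

    ``features`` may be a raw (n, 3C) matrix with ``labels``, or a feature
    table carrying ``label`` and the contract feature columns.
    """
    if isinstance(features, pd.DataFrame):
        if labels is None:
            labels = features["label"].to_numpy(dtype=int)
        names = [c for c in features.columns if c.split("_")[0] in ("rms", "mav", "var")]
        x = features[names].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels required with a raw feature matrix")
        if channel_names is not None:
            names = _feature_names(channel_names)
        else:
            names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature/label length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes")
    est = ExtraTreesClassifier(n_estimators=n_trees, random_state=int(seed), n_jobs=1)
    est.fit(x, y)
    return GestureModel(
        estimator=est,
        feature_names=list(names),
        strategy=TrainingStrategy.parse(strategy) if strategy is not None else None,
        seed=int(seed),
    )


def predict_proba(model: GestureModel, z: np.ndarray) -> np.ndarray:
    """Probability vectors over all 14 classes; absent classes get 0.

    Accepts one feature vector (3C,) or a stack (n, 3C); always returns
    (n, 14) rows summing to 1.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature length {z.shape[1]} does not match the model contract "
            f"({len(model.feature_names)})"
        )
    p = model.estimator.predict_proba(z)
    out = np.zeros((z.shape[0], model.n_classes))
    out[:, model.estimator.classes_.astype(int)] = p
    return out
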