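"""HDF5 / CSV / JSON persistence for sessions and pipeline artifacts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import EmgRecording, PhaseTimeline
from .synth import (
    ActivationProfile,
    SyntheticProtocolConfig,
    SyntheticSession,
    SyntheticTrial,
)

__all__ = [
    "canonical_json",
    "write_json",
    "read_json",
    "config_digest",
    "save_session",
    "load_session",
    "recording_to_csv",
]


def canonical_json(obj) -> str:
    """Deterministic JSON text (sorted keys, stable float repr)."""
    return json.dumps(obj, sort_keys=True, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: Path) -> None:
    Path(path).write_text(canonical_json(obj) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())


def config_digest(obj) -> str:
    """Content hash of a (nested-dataclass) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()[:16]


def save_session(session: SyntheticSession, path: Path) -> None:
    """Session signals + ground truth to one HDF5 file (dataset per trial)."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = canonical_json(dataclasses.asdict(session.config))
        f.attrs["manifest"] = canonical_json(session.manifest)
        f.attrs["profile_grasp"] = session.profile.grasp
        f.attrs["profile_rest"] = session.profile.rest
        g_tr = f.create_group("trials")
        for t in session.trials:
            g = g_tr.create_group(t.trial_id)
            g.create_dataset("data", data=t.recording.samples)
            g.attrs["fs"] = t.recording.fs
            g.attrs["gesture"] = t.gesture
            g.attrs["object_id"] = t.object_id
            g.attrs["trial_index"] = t.trial_index
            g.attrs["breakpoints_ms"] = np.asarray(t.timeline.breakpoints_ms)
            g.attrs["trial_length_ms"] = t.timeline.trial_length_ms
        g_mvc = f.create_group("mvc")
        for name, rec in session.mvc.items():
            d = g_mvc.create_dataset(name, data=rec.samples)
            d.attrs["fs"] = rec.fs


def load_session(path: Path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        config = SyntheticProtocolConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in json.loads(f.attrs["config"]).items()}
        )
        manifest = json.loads(f.attrs["manifest"])
        profile = ActivationProfile(
            grasp=np.asarray(f.attrs["profile_grasp"]),
            rest=np.asarray(f.attrs["profile_rest"]),
            reach_blend=config.reach_blend,
            return_blend=config.return_blend,
            ramp_ms=config.ramp_ms,
        )
        trials = []
        for tid in sorted(f["trials"]):
            g = f["trials"][tid]
            rec = EmgRecording(
                samples=g["data"][()],
                fs=float(g.attrs["fs"]),
                channel_names=config.channel_names,
                meta={"gesture": int(g.attrs["gesture"]),
                      "object": int(g.attrs["object_id"]),
                      "trial": int(g.attrs["trial_index"])},
            )
            timeline = PhaseTimeline(
                float(g.attrs["trial_length_ms"]),
                tuple(np.asarray(g.attrs["breakpoints_ms"]).tolist()),
            )
            trials.append(SyntheticTrial(
                rec, timeline, int(g.attrs["gesture"]),
                int(g.attrs["object_id"]), int(g.attrs["trial_index"]),
            ))
        trials.sort(key=lambda t: (t.object_id, t.trial_index))
        mvc = {
            name: EmgRecording(
                samples=f["mvc"][name][()],
                fs=float(f["mvc"][name].attrs["fs"]),
                channel_names=config.channel_names,
                meta={"mvc_target": name},
            )
            for name in sorted(f["mvc"])
        }
    return SyntheticSession(config, profile, trials, mvc, manifest)


def recording_to_csv(rec: EmgRecording, path: Path) -> None:
    """One column per channel, header = muscle abbreviations."""
    pd.DataFrame(rec.samples.T, columns=list(rec.channel_names)).to_csv(path, index=False)
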