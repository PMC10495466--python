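"""Session persistence: HDF5 container and CSV behavioral export."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .session import SessionData

__all__ = ["save_session", "load_session", "behavior_frame", "export_behavior_csv"]


def save_session(path, session: SessionData, name: str = "session") -> None:
    """Write a session to an HDF5 file (one group per session)."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("voltages", data=session.voltages, compression="gzip", shuffle=True)
        g.attrs["fs"] = session.fs
        g.attrs["markers"] = json.dumps({k: int(v) for k, v in session.markers.items()})
        g.create_dataset("task", data=np.asarray(session.task, dtype="S"))
        g.create_dataset("outcome", data=np.asarray(session.outcome, dtype=bool))
        g.create_dataset("reaction_time_ms", data=np.asarray(session.reaction_time_ms, dtype=float))
        if session.ground_truth is not None:
            gt = g.create_group("ground_truth")
            for k, v in session.ground_truth.items():
                gt.create_dataset(k, data=np.asarray(v))


def load_session(path, name: str = "session") -> SessionData:
    with h5py.File(path, "r") as f:
        g = f[name]
        gt = None
        if "ground_truth" in g:
            gt = {k: np.asarray(v) for k, v in g["ground_truth"].items()}
        return SessionData(
            voltages=np.asarray(g["voltages"]),
            fs=float(g.attrs["fs"]),
            task=np.array([t.decode() for t in g["task"]], dtype=object),
            outcome=np.asarray(g["outcome"], dtype=bool),
            reaction_time_ms=np.asarray(g["reaction_time_ms"], dtype=float),
            markers=json.loads(g.attrs["markers"]),
            ground_truth=gt,
        )


def behavior_frame(session: SessionData) -> pd.DataFrame:
    """Per-trial behavioral table (task, outcome, reaction time)."""
    return pd.DataFrame(
        {
            "trial": np.arange(session.n_trials),
            "task": np.asarray(session.task, dtype=str),
            "correct": np.asarray(session.outcome, dtype=bool),
            "reaction_time_ms": np.asarray(session.reaction_time_ms, dtype=float),
        }
    )


def export_behavior_csv(path, session: SessionData) -> None:
    behavior_frame(session).to_csv(path, index=False)
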