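"""HDF5 session container and ground-truth sidecar tables.

Layout: groups ``/frames`` (per-frame behavior), ``/trials`` (trial
metadata), ``/neurons`` (``dff`` and ``events`` arrays) and ``/meta``
(scalar attributes).  Ground truth is exported as a TSV sidecar.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synthetic import GroundTruth, Session

_FRAME_COLS = ("time_s", "trial", "position_cm", "speed_cms", "lick", "teleport")
_TRIAL_COLS = ("zone", "zone_start_cm", "rewarded", "omission",
               "reward_pos_cm", "teleport_distance_cm")


def save_session(session: Session, path):
    with h5py.File(path, "w") as f:
        g = f.create_group("frames")
        for c in _FRAME_COLS:
            g.create_dataset(c, data=session.frames[c].to_numpy())
        g = f.create_group("trials")
        for c in _TRIAL_COLS:
            data = session.trials[c].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(c, data=data)
        g = f.create_group("neurons")
        g.create_dataset("dff", data=session.dff, compression="gzip")
        g.create_dataset("events", data=session.events, compression="gzip")
        m = f.create_group("meta")
        m.attrs["frame_rate_hz"] = session.frame_rate_hz
        m.attrs["track_length_cm"] = session.track_length_cm
        m.attrs["n_bins"] = session.n_bins
        m.attrs["zone_length_cm"] = session.zone_length_cm
        m.attrs["meta_json"] = json.dumps(session.meta)


def load_session(path) -> Session:
    with h5py.File(path, "r") as f:
        frames = pd.DataFrame({c: f["frames"][c][()] for c in _FRAME_COLS})
        trials = {}
        for c in _TRIAL_COLS:
            d = f["trials"][c][()]
            if d.dtype.kind == "S":
                d = d.astype(str)
            trials[c] = d
        trials = pd.DataFrame(trials)
        trials.index.name = "trial"
        m = f["meta"].attrs
        return Session(
            frames=frames, trials=trials,
            dff=f["neurons"]["dff"][()], events=f["neurons"]["events"][()],
            frame_rate_hz=float(m["frame_rate_hz"]),
            track_length_cm=float(m["track_length_cm"]),
            n_bins=int(m["n_bins"]),
            zone_length_cm=float(m["zone_length_cm"]),
            meta=json.loads(m["meta_json"]),
        )


def save_ground_truth(gt: GroundTruth, path):
    gt.table.to_csv(path, sep="\t")


def load_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="neuron")
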