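"""Session bundle and ground-truth serialization.

HDF5 schema for a session::

    /rest1, /run, /rest2          frames x neurons float64
    /behaviour/position_cm        per RUN frame
    /behaviour/velocity_cm_s      per RUN frame
    /rest1_movement_mask          bool per REST1 frame
    /rest2_movement_mask          bool per REST2 frame
    /lfp/rest1, /lfp/rest2        optional voltage traces
    attrs: JSON-encoded SimConfig under 'config'

Ground truth is stored as plain JSON.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .synthetic import GroundTruth, SessionBundle, SimConfig

__all__ = ["save_session", "load_session", "save_truth", "load_truth"]


def save_session(path, bundle: SessionBundle) -> None:
    with h5py.File(path, "w") as f:
        for name in ("rest1", "run", "rest2"):
            f.create_dataset(name, data=getattr(bundle, name))
        g = f.create_group("behaviour")
        g.create_dataset("position_cm", data=bundle.position_cm)
        g.create_dataset("velocity_cm_s", data=bundle.velocity_cm_s)
        f.create_dataset("rest1_movement_mask",
                         data=bundle.rest1_movement_mask.astype(bool))
        f.create_dataset("rest2_movement_mask",
                         data=bundle.rest2_movement_mask.astype(bool))
        if bundle.lfp_rest1 is not None or bundle.lfp_rest2 is not None:
            lg = f.create_group("lfp")
            if bundle.lfp_rest1 is not None:
                lg.create_dataset("rest1", data=bundle.lfp_rest1)
            if bundle.lfp_rest2 is not None:
                lg.create_dataset("rest2", data=bundle.lfp_rest2)
        if bundle.meta is not None:
            f.attrs["config"] = json.dumps(bundle.meta.to_dict())


def load_session(path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        meta = None
        if "config" in f.attrs:
            meta = SimConfig.from_dict(json.loads(f.attrs["config"]))
        lfp1 = lfp2 = None
        if "lfp" in f:
            if "rest1" in f["lfp"]:
                lfp1 = f["lfp/rest1"][()]
            if "rest2" in f["lfp"]:
                lfp2 = f["lfp/rest2"][()]
        return SessionBundle(
            rest1=f["rest1"][()], run=f["run"][()], rest2=f["rest2"][()],
            position_cm=f["behaviour/position_cm"][()],
            velocity_cm_s=f["behaviour/velocity_cm_s"][()],
            rest1_movement_mask=f["rest1_movement_mask"][()].astype(bool),
            rest2_movement_mask=f["rest2_movement_mask"][()].astype(bool),
            lfp_rest1=lfp1, lfp_rest2=lfp2, meta=meta)


def save_truth(path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
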