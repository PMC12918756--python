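"""HDF5/CSV/JSON file glue for recordings, projectors, gains and reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .projection import GainVector, Projector, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_projector",
    "load_projector",
    "save_gains_csv",
    "load_gains_csv",
    "write_json",
]


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to HDF5 (datasets /data, /fs, /channel_ids, /active_mask)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.B)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_ids", data=np.array(rec.channel_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset("active_mask", data=rec.active_mask.astype(np.uint8))


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        ids = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_ids"][()])
        mask = f["active_mask"][()].astype(bool) if "active_mask" in f else None
    return Recording(data, fs, ids, active_mask=mask)


def save_projector(proj: Projector, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("P", data=proj.P)
        f.attrs["method"] = proj.method
        f.attrs["basis_order"] = proj.basis_order


def load_projector(path: str | Path) -> Projector:
    with h5py.File(path, "r") as f:
        return Projector(f["P"][()], str(f.attrs["method"]), int(f.attrs["basis_order"]))


def save_gains_csv(
    gains: GainVector, channel_ids: tuple[str, ...], rejected: tuple[str, ...], path: str | Path
) -> None:
    """Gain table: channel_id, gain, rejected flag."""
    pd.DataFrame(
        {
            "channel_id": channel_ids,
            "gain": gains.c,
            "rejected": [cid in rejected for cid in channel_ids],
        }
    ).to_csv(path, index=False)


def load_gains_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    """JSON with numpy scalars/arrays coerced to plain Python."""

    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON-serialisable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
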