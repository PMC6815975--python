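"""Plain-text I/O for recordings and result tables.

Recordings are exchanged as a two-column numeric text matrix (one row per
sample, left and right channel in uV) with a one-line ``fs=<Hz>`` header,
optionally extended with ``t0_post_rosc_min=`` and ``animal_id=`` fields.
Tables are CSV with a comment header carrying the master seed and a config
hash so every output is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import Recording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "write_table",
    "config_hash",
]


def write_recording_text(rec: Recording, path) -> None:
    header = (f"fs={rec.fs:g} t0_post_rosc_min={rec.t0_post_rosc_min:g} "
              f"animal_id={rec.animal_id}")
    np.savetxt(path, rec.data.T, fmt="%.4f", header=header, comments="# ")


def read_recording_text(path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    for tok in first.lstrip("# ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    if "fs" not in meta:
        raise ValueError(f"{path}: missing fs= header")
    data = np.loadtxt(path)
    return Recording(data=np.atleast_2d(data).T if data.ndim == 2 else data,
                     fs=float(meta["fs"]),
                     animal_id=meta.get("animal_id", path.stem),
                     t0_post_rosc_min=float(meta.get("t0_post_rosc_min", 0)))


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable config representation."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int, cfg_hash: str) -> None:
    """CSV with a traceability comment header (seed + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
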