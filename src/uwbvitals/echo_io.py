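"""Echo-matrix container I/O.

The on-disk container is an HDF5 file with datasets/attributes
``{data, Ts, Tf, fc}``; small matrices can also round-trip through a CSV
(one row per slow-time frame) whose header comments carry the sampling
metadata.  Ground-truth target records are written as plain CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .signal_model import EchoMatrix, TargetTruth

__all__ = ["save_echo", "load_echo", "echo_to_csv", "echo_from_csv",
           "truth_to_csv", "truth_from_csv"]


def save_echo(path: str | Path, echo: EchoMatrix) -> None:
    with h5py.File(path, "w") as fh:
        # track_times=False keeps files byte-identical across runs
        dset = fh.create_dataset("data", data=echo.data, track_times=False)
        dset.attrs["Ts"] = echo.ts
        dset.attrs["Tf"] = echo.tf
        dset.attrs["fc"] = echo.fc


def load_echo(path: str | Path) -> EchoMatrix:
    with h5py.File(path, "r") as fh:
        dset = fh["data"]
        return EchoMatrix(data=dset[()], ts=float(dset.attrs["Ts"]),
                          tf=float(dset.attrs["Tf"]),
                          fc=float(dset.attrs["fc"]))


def echo_to_csv(path: str | Path, echo: EchoMatrix) -> None:
    """One slow-time frame per row; metadata in '#'-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write(f"# Ts={echo.ts!r}\n# Tf={echo.tf!r}\n# fc={echo.fc!r}\n")
        np.savetxt(fh, echo.data, delimiter=",")


def echo_from_csv(path: str | Path) -> EchoMatrix:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("=")
            meta[key.strip()] = float(val)
    data = np.loadtxt(path, delimiter=",", comments="#")
    return EchoMatrix(data=np.atleast_2d(data), ts=meta["Ts"],
                      tf=meta["Tf"], fc=meta["fc"])


def truth_to_csv(records: Sequence[TargetTruth], path: str | Path) -> None:
    pd.DataFrame([{
        "person_id": r.person_id,
        "range_m": r.range_m,
        "azimuth_deg": r.azimuth_deg,
        "fr_hz": r.fr_hz,
        "fh_hz": r.fh_hz,
    } for r in records],
        columns=["person_id", "range_m", "azimuth_deg", "fr_hz", "fh_hz"],
    ).to_csv(path, index=False)


def truth_from_csv(path: str | Path) -> list[TargetTruth]:
    df = pd.read_csv(path)
    return [TargetTruth(person_id=int(r.person_id), range_m=float(r.range_m),
                        bin=-1, azimuth_deg=float(r.azimuth_deg),
                        fr_hz=float(r.fr_hz), fh_hz=float(r.fh_hz))
            for r in df.itertuples()]
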