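"""Plain-text and TIFF I/O for traces, tracks, images, and ground truth.

CSV layouts are fixed:

* traces:  trace_id, vertex_index, x_um, y_um
* tracks:  track_id, frame, t_min, x_um [, y_um] [, treatment_time_min]

All CSV writers use one float format so identical data produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import TimeLapseTrack
from .stripe_guidance import NeuriteTrace

CSV_FLOAT_FORMAT = "%.9g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_traces_csv(traces: list[NeuriteTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.vertices):
            rows.append({"trace_id": tr.trace_id, "vertex_index": i,
                         "x_um": x, "y_um": y})
    write_csv(pd.DataFrame(rows), path)


def read_traces_csv(path: str | Path) -> list[NeuriteTrace]:
    df = pd.read_csv(path)
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("vertex_index")
        traces.append(NeuriteTrace(trace_id=tid,
                                   vertices=grp[["x_um", "y_um"]].to_numpy()))
    return traces


def write_tracks_csv(tracks: list[TimeLapseTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        p = tr.positions
        for i, t in enumerate(tr.t_min):
            row = {"track_id": tr.track_id, "frame": i, "t_min": t}
            if p.ndim == 1:
                row["x_um"] = p[i]
            else:
                row["x_um"] = p[i, 0]
                row["y_um"] = p[i, 1]
            if tr.treatment_time_min is not None:
                row["treatment_time_min"] = tr.treatment_time_min
            rows.append(row)
    write_csv(pd.DataFrame(rows), path)


def read_tracks_csv(path: str | Path) -> list[TimeLapseTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        if "y_um" in grp.columns and grp["y_um"].notna().any():
            pos = grp[["x_um", "y_um"]].to_numpy()
        else:
            pos = grp["x_um"].to_numpy()
        tt = None
        if "treatment_time_min" in grp.columns and grp["treatment_time_min"].notna().any():
            tt = float(grp["treatment_time_min"].iloc[0])
        tracks.append(TimeLapseTrack(track_id=tid, t_min=grp["t_min"].to_numpy(),
                                     positions=pos, treatment_time_min=tt))
    return tracks


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
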