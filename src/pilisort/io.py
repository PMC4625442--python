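"""Readers and writers for the package's on-disk formats.

Images and masks are multi-page TIFF (one file per channel), tables are CSV
with a header naming the coordinate convention, fits and ground truth are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
import tifffile

from .clonedyn import FrontTrace
from .colonyimg import ColonyTrack
from .trapforce import RetractionEvent


def write_stack_tiff(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, np.float32))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trace_csv(path: str | Path, time_s: np.ndarray, deflection_nm: np.ndarray) -> None:
    pd.DataFrame({"time_s": time_s, "deflection_nm": deflection_nm}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["deflection_nm"].to_numpy()


def write_events_csv(path: str | Path, events: Sequence[RetractionEvent]) -> None:
    pd.DataFrame(
        {
            "t_start_s": [e.t_start for e in events],
            "t_rupture_s": [e.t_rupture for e in events],
            "force_pN": [e.rupture_force for e in events],
            "above_linear_range": [e.above_linear_range for e in events],
        }
    ).to_csv(path, index=False)


def write_tracks_csv(path: str | Path, tracks: Iterable[ColonyTrack]) -> None:
    rows: List[dict] = []
    for tr in tracks:
        for f, (x, y), r, v in zip(tr.frames, tr.centers, tr.radii, tr.valid):
            rows.append(
                {"frame": f, "track_id": tr.track_id, "x_px": x, "y_px": y, "R_px": r, "valid": v}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_front_traces_csv(path: str | Path, traces: Sequence[FrontTrace]) -> None:
    rows = []
    for tr in traces:
        for f, d in zip(tr.frames, tr.distances):
            rows.append({"clone_id": tr.clone_id, "frame": int(f), "distance_um": d})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, obj: object) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
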