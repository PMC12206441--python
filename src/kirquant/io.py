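"""File I/O: trace CSVs, multi-page TIFFs, annotation tables.

Trace CSVs carry columns ``time_s, v_mV, i_pA``; per-cell metadata
(capacitance, condition, group) live in a sidecar table so one pairs file
can drive a whole analysis run.  Images move as multi-page TIFF with the
channel order nuclei, marker, target; label masks are written as 16-bit
TIFF.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ephys import RampRecording
from .image_quant import MultiChannelImage

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_pairs_table",
    "read_pairs_table",
    "write_multichannel_tiff",
    "read_multichannel_tiff",
    "write_label_tiff",
    "read_yaml",
]

TRACE_COLUMNS = ["time_s", "v_mV", "i_pA"]


def write_trace_csv(rec: RampRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.time, "v_mV": rec.v_cmd, "i_pA": rec.i}
    ).to_csv(path, index=False)


def read_trace_csv(
    path: str | Path,
    capacitance_pf: float,
    condition: str,
    cell_id: str,
    group: str = "other",
) -> RampRecording:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    hz = 1.0 / float(np.median(dt)) if dt.size else 10_000.0
    return RampRecording(
        time=t,
        v_cmd=df["v_mV"].to_numpy(dtype=float),
        i=df["i_pA"].to_numpy(dtype=float),
        capacitance_pf=capacitance_pf,
        condition=condition,  # type: ignore[arg-type]
        cell_id=cell_id,
        sampling_hz=hz,
        group=group,
    )


PAIRS_COLUMNS = ["cell_id", "group", "capacitance_pf", "control_path", "ba_path"]


def write_pairs_table(rows: Iterable[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows))[PAIRS_COLUMNS].to_csv(path, index=False)


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PAIRS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table {path} missing columns {sorted(missing)}")
    return df


def write_multichannel_tiff(image: MultiChannelImage, path: str | Path) -> None:
    stack = np.stack([image.nuclei, image.marker, image.target]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_multichannel_tiff(
    path: str | Path,
    pixel_size_um: float = 1.0,
    image_id: str | None = None,
    channel_order: tuple[int, int, int] = (0, 1, 2),
) -> MultiChannelImage:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError(f"{path}: expected a 3-page (nuclei, marker, target) TIFF")
    n, m, t = channel_order
    return MultiChannelImage(
        nuclei=np.asarray(stack[n], dtype=float),
        marker=np.asarray(stack[m], dtype=float),
        target=np.asarray(stack[t], dtype=float),
        pixel_size_um=pixel_size_um,
        image_id=image_id if image_id is not None else Path(path).stem,
    )


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
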