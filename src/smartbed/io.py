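"""Plain-text I/O for frames, datasets, risk tables and control outputs.

Frames travel as 32x64 comma-separated matrices; a dataset directory holds
one CSV per frame plus a ``labels.csv`` sidecar (file, posture_index,
subject_id).  Per-sequence slat tables and control outputs are CSVs shaped
like the bed's operator reports.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .fuzzy import ControlOutput
from .preprocess import N_HOPB, HoPBLevels
from .synthetic import FrameDataset, PressureFrame


def write_frame_csv(frame: PressureFrame, path: str | Path) -> None:
    np.savetxt(path, frame.values, fmt="%.6g", delimiter=",")


def read_frame_csv(path: str | Path, timestamp_period: int = 0) -> PressureFrame:
    return PressureFrame(np.loadtxt(path, delimiter=","), timestamp_period)


def write_dataset(dataset: FrameDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, label, subject) in enumerate(
            zip(dataset.frames, dataset.labels, dataset.subjects)):
        name = f"frame_{i:05d}.csv"
        write_frame_csv(frame, out / name)
        rows.append({"file": name, "posture_index": int(label),
                     "subject_id": int(subject)})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def read_dataset(in_dir: str | Path) -> tuple[list[PressureFrame], np.ndarray]:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv")
    frames = [read_frame_csv(in_dir / f) for f in labels["file"]]
    return frames, labels["posture_index"].to_numpy()


def levels_table(levels: HoPBLevels, period: int = 0) -> pd.DataFrame:
    """One period's slat table: (period, hopb, heat, level, phase, time_level)."""
    return pd.DataFrame({
        "period": period,
        "hopb": np.arange(1, N_HOPB + 1),
        "heat": levels.heat,
        "level": levels.level,
        "phase": levels.phase,
        "time_level": levels.time_level,
    })


def read_levels_csv(path: str | Path, index_base: int = 1) -> HoPBLevels:
    """Read a slat table; ``index_base`` accepts 0- or 1-based hopb columns."""
    df = pd.read_csv(path).sort_values("hopb")
    if len(df) != N_HOPB:
        raise ValueError(f"expected {N_HOPB} rows, got {len(df)}")
    expected_first = index_base
    if int(df["hopb"].iloc[0]) != expected_first:
        raise ValueError(f"hopb column does not start at {expected_first}")
    return HoPBLevels(
        heat=df["heat"].to_numpy(float),
        level=df["level"].to_numpy(int),
        phase=df["phase"].to_numpy(int),
        time_level=df["time_level"].to_numpy(int),
    )


def write_control_csv(control: ControlOutput, path: str | Path) -> None:
    pd.DataFrame({"hopb_num": np.arange(1, N_HOPB + 1),
                  "setting": control.settings}).to_csv(path, index=False)


def write_run_log(log: list[dict], path: str | Path) -> None:
    """Per-period state log CSV: one row per (period, hopb) with the slat's
    ulcer level, time level, optimized setting and resulting height."""
    rows = []
    for rec in log:
        for i in range(N_HOPB):
            rows.append({
                "period": rec["period"],
                "hopb": i + 1,
                "decubitus": rec["posture"] if rec["posture"] is not None else -1,
                "ulcer_level": int(rec["levels"][i]) if "levels" in rec else 0,
                "time": int(rec["time_levels"][i]) if "time_levels" in rec else 0,
                "optimized_setting": rec["settings"][i],
                "height_mm": rec["heights"][i],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
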