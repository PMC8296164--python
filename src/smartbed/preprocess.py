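"""Pressure-frame preprocessing: pooling, heat units, ulcer levels, splits.

The 32x64 sensor image is pooled onto the bed's actuator geometry — 20
height-adjustable slats (HoPBs) head-to-foot, 10 pooled cells across each —
with exact fractional area-overlap weights (the 3.2x down-sampling factor is
non-integer).  Per-slat "heat units" are the mean pooled pressure of a slat;
a sample-wide calibration pins the mean nonzero heat to ulcer level 10 and
the sample maximum to level 20, and integer levels bin into linguistic ulcer
phases 1-5 used as fuzzy antecedents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic import N_COLS, N_ROWS, PostureLabel, PressureFrame

N_HOPB = 20  #: slats along the bed's long axis
SENSORS_PER_HOPB = 10  #: pooled cells across each slat
CELL_AREA = (N_ROWS / SENSORS_PER_HOPB) * (N_COLS / N_HOPB)  # 3.2 * 3.2

MAX_LEVEL = 20
MEAN_LEVEL = 10
MAX_TIME_LEVEL = 8


@dataclass
class HoPBGrid:
    """Pooled pressure on the slat grid: 20 slats (head->foot) x 10 cells."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_HOPB, SENSORS_PER_HOPB):
            raise ValueError(
                f"grid must be {N_HOPB}x{SENSORS_PER_HOPB}, got {self.values.shape}"
            )
        if self.values.min() < 0:
            raise ValueError("pooled pressures must be non-negative")


@dataclass(frozen=True)
class CalibrationStats:
    """Sample-wide heat calibration anchors.

    mean_nonzero is the mean of all strictly positive heats in the
    calibration sample (pinned to ulcer level 10); max_pressure is the sample
    maximum (pinned to level 20).
    """

    mean_nonzero: float
    max_pressure: float

    def __post_init__(self) -> None:
        if not (self.max_pressure >= self.mean_nonzero > 0):
            raise ValueError("need max_pressure >= mean_nonzero > 0")


@dataclass
class HoPBLevels:
    """Per-slat risk state: continuous heat, integer level 0-20, phase 0-5,
    and time-in-posture level 1-8 (0 allowed for never-contacted slats)."""

    heat: np.ndarray
    level: np.ndarray
    phase: np.ndarray
    time_level: np.ndarray

    def __post_init__(self) -> None:
        for name in ("heat", "level", "phase", "time_level"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (N_HOPB,):
                raise ValueError(f"{name} must have shape ({N_HOPB},)")
            setattr(self, name, arr)
        if np.any((self.level == 0) != (self.phase == 0)):
            raise ValueError("level and phase must vanish together")


def _overlap_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) matrix of fractional interval overlaps.

    Row i holds the length of [i*f, (i+1)*f) covered by each unit sensor
    interval [j, j+1), f = n_in/n_out; rows sum to f.
    """
    f = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * f, (i + 1) * f
        j0, j1 = int(math.floor(lo)), min(int(math.ceil(hi)), n_in)
        for j in range(j0, j1):
            w[i, j] = max(0.0, min(hi, j + 1) - max(lo, j))
    return w


_W_ROWS = _overlap_weights(N_ROWS, SENSORS_PER_HOPB) / (N_ROWS / SENSORS_PER_HOPB)
_W_COLS = _overlap_weights(N_COLS, N_HOPB) / (N_COLS / N_HOPB)


def pool_frame(frame: PressureFrame | np.ndarray) -> HoPBGrid:
    """Area-weighted average pooling of a 32x64 frame onto the 20x10 slat grid.

    Each output cell is the area-weighted mean pressure over its fractional
    3.2x3.2 sensor footprint, so pooling preserves constants and conserves
    total load (sum(grid) * cell area == sum(frame)).
    """
    values = frame.values if isinstance(frame, PressureFrame) else np.asarray(frame, float)
    if values.shape != (N_ROWS, N_COLS):
        raise ValueError(f"expected a {N_ROWS}x{N_COLS} frame, got {values.shape}")
    pooled = _W_ROWS @ values @ _W_COLS.T  # (10, 20)
    return HoPBGrid(pooled.T)


def hopb_heat(grid: HoPBGrid | np.ndarray) -> np.ndarray:
    """Heat units per slat: the mean of its 10 pooled cells (pressure per
    unit slat area, the quantity the risk threshold is framed in)."""
    values = grid.values if isinstance(grid, HoPBGrid) else np.asarray(grid, float)
    if values.shape != (N_HOPB, SENSORS_PER_HOPB):
        raise ValueError("expected a 20x10 pooled grid")
    return values.mean(axis=1)


def calibrate(heats: Iterable[float] | np.ndarray) -> CalibrationStats:
    """Calibration anchors over a sample of heats (all slats, all frames)."""
    arr = np.asarray(list(heats) if not isinstance(heats, np.ndarray) else heats,
                     dtype=float).ravel()
    if arr.size and arr.min() < 0:
        raise ValueError("heats must be non-negative")
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("cannot calibrate: no nonzero heat in the sample")
    return CalibrationStats(float(positive.mean()), float(arr.max()))


def continuous_levels(heats: np.ndarray, stats: CalibrationStats) -> np.ndarray:
    """Pre-rounding ulcer levels: 0 at no contact, 10 at the calibration
    mean, 20 at the calibration maximum, piecewise-linear in between and
    clamped at 20 above the maximum."""
    heats = np.asarray(heats, dtype=float)
    if heats.size and heats.min() < 0:
        raise ValueError("heats must be non-negative")
    mean, mx = stats.mean_nonzero, stats.max_pressure
    out = np.zeros_like(heats)
    low = (heats > 0) & (heats <= mean)
    out[low] = MEAN_LEVEL * heats[low] / mean
    high = heats > mean
    if mx > mean:
        out[high] = MEAN_LEVEL + MEAN_LEVEL * (heats[high] - mean) / (mx - mean)
    else:  # degenerate: every positive heat equals the maximum
        out[high] = MAX_LEVEL
    return np.minimum(out, MAX_LEVEL)


def assign_levels(heats: np.ndarray, stats: CalibrationStats) -> np.ndarray:
    """Integer ulcer levels 0-20 per slat (round-half-up of the continuous
    piecewise-linear map; rounding is platform-independent by construction)."""
    cont = continuous_levels(heats, stats)
    levels = np.floor(cont + 0.5).astype(int)
    levels[np.asarray(heats) == 0] = 0
    return np.minimum(levels, MAX_LEVEL)


def level_to_phase(level: int | np.ndarray) -> int | np.ndarray:
    """Bin an integer ulcer level into a linguistic phase.

    0 -> 0 (no contact); 1-4 -> 1; 5-8 -> 2; 9-12 -> 3; 13-16 -> 4;
    17-20 -> 5.  Width-4 bins yield the five phases of the rule grammar.
    """
    arr = np.asarray(level)
    if np.any((arr < 0) | (arr > MAX_LEVEL)):
        raise ValueError(f"levels must lie in [0, {MAX_LEVEL}]")
    phase = np.ceil(arr / 4).astype(int)
    return int(phase) if np.isscalar(level) else phase


def accumulate_time(history: Sequence[PostureLabel | int]) -> int:
    """Time-in-posture level 1-8 from a per-period posture history.

    Counts the trailing run k of the current posture (one entry per 80 s
    period; a posture change resets the count) and bins it to
    min(8, ceil(k/2)).
    """
    if len(history) == 0:
        raise ValueError("posture history is empty")

    def idx(p: PostureLabel | int) -> int:
        return p.index if isinstance(p, PostureLabel) else int(p)

    current = idx(history[-1])
    k = 0
    for p in reversed(history):
        if idx(p) != current:
            break
        k += 1
    return min(MAX_TIME_LEVEL, math.ceil(k / 2))


def time_to_level(k: int) -> int:
    """Bin an accumulated period count to a time level 1-8 (0 stays 0)."""
    if k < 0:
        raise ValueError("period count must be non-negative")
    return min(MAX_TIME_LEVEL, math.ceil(k / 2))


def split_dataset(
    n: int,
    n_partitions: int = 5,
    n_train_partitions: int = 4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random 5-fold style split: one held-out fold of size ceil(n/5).

    Reproduces an 80/20 partition (e.g. n = 20,024 -> 16,019 train /
    4,005 test).  Returns disjoint (train, test) index arrays covering
    range(n).
    """
    if n < n_partitions:
        raise ValueError(f"need n >= {n_partitions} samples to split")
    if not 1 <= n_train_partitions < n_partitions:
        raise ValueError("invalid partition counts")
    perm = np.random.default_rng(seed).permutation(n)
    test_size = math.ceil(n / n_partitions) * (n_partitions - n_train_partitions)
    test_size = min(test_size, n - 1)
    return np.sort(perm[test_size:]), np.sort(perm[:test_size])
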