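"""Closed-loop bed simulator: sense -> classify -> score -> infer -> actuate.

Each 80 s control period, one pressure frame is pooled onto the slat grid,
the posture classifier labels the occupant, per-slat ulcer levels and
dwell-time levels are updated, the Mamdani controller produces one crisp
movement setting per slat, and the 20 actuators move (clamped to the +/-40 mm
hardware range).  A simple load-conserving redistribution model lets lowered
slats shed pressure onto the remaining contact slats, which closes the loop.
The simulator also emits the caregiver guidance report: posture status,
ulcer regions and phases, contacted slats, and a recommended position change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .classifier import ConvLSTMClassifier
from .fuzzy import (
    DEFAULT_REGION_MAPS,
    ControlOutput,
    FuzzyEngine,
    RiskConfig,
    region_of_slat,
)
from .preprocess import (
    N_HOPB,
    CalibrationStats,
    HoPBLevels,
    assign_levels,
    hopb_heat,
    level_to_phase,
    pool_frame,
    time_to_level,
)
from .synthetic import N_COLS, N_ROWS, PostureLabel, PressureFrame
from .preprocess import _overlap_weights

MAX_HEIGHT_MM = 40.0
DEFAULT_GAIN_MM = 20.0  # mm per output unit: [-2, 2] spans the +/-40 mm range

# fractional membership of each of the 64 length-axis columns in each slat
_COL_TO_SLAT = _overlap_weights(N_COLS, N_HOPB).T  # (64, 20), rows sum to 1
_COL_TO_SLAT = _COL_TO_SLAT / _COL_TO_SLAT.sum(axis=1, keepdims=True)


@dataclass
class BedState:
    """Actuator heights, per-slat dwell counters, risk levels, and period."""

    heights: np.ndarray = field(default_factory=lambda: np.zeros(N_HOPB))
    posture_history: list[int] = field(default_factory=list)
    levels: HoPBLevels | None = None
    period: int = 0
    dwell: np.ndarray = field(default_factory=lambda: np.zeros(N_HOPB, dtype=int))

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (N_HOPB,):
            raise ValueError(f"need {N_HOPB} heights")
        if np.abs(self.heights).max() > MAX_HEIGHT_MM:
            raise ValueError(f"|height| must be <= {MAX_HEIGHT_MM} mm")
        if self.period < 0:
            raise ValueError("period must be >= 0")

    @property
    def posture(self) -> int | None:
        return self.posture_history[-1] if self.posture_history else None


@dataclass
class GuidanceReport:
    """Caregiver-facing summary of the current state."""

    recommended_position_change: str
    current_posture: str
    ulcer_areas: list[tuple[int, str]]  # (1-based slat, body-region name)
    ulcer_phases: list[int]  # phase per listed area
    contact_hopbs: list[int]  # 1-based slats currently in contact

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GuidanceReport":
        d = json.loads(text)
        d["ulcer_areas"] = [tuple(a) for a in d["ulcer_areas"]]
        return cls(**d)

    def to_text(self) -> str:
        lines = [f"Recommended position change: {self.recommended_position_change}",
                 f"Lying position: {self.current_posture}"]
        if self.ulcer_areas:
            for (slat, region), phase in zip(self.ulcer_areas, self.ulcer_phases):
                lines.append(f"Ulcer risk at HoPB {slat} ({region}): phase {phase}")
        else:
            lines.append("No ulcer-risk areas detected")
        lines.append("Contact HoPBs: " + ", ".join(map(str, self.contact_hopbs)))
        return "\n".join(lines)


def apply_settings(state: BedState, control: ControlOutput,
                   gain: float = DEFAULT_GAIN_MM) -> BedState:
    """Move the actuators: height += gain * setting, clamped to +/-40 mm."""
    settings = control.settings
    if not np.all(np.isfinite(settings)):
        raise ValueError("non-finite control setting")
    state.heights = np.clip(state.heights + gain * settings,
                            -MAX_HEIGHT_MM, MAX_HEIGHT_MM)
    return state


def redistribute_pressure(frame: PressureFrame, heights: np.ndarray) -> PressureFrame:
    """Shed load from lowered slats onto the rest, conserving total load.

    Each slat attenuates its columns by f_i = max(0, 1 + height_i/40), so a
    fully lowered slat (-40 mm) carries nothing; the shed load is reassigned
    proportionally to the remaining contact, keeping the frame total constant.
    If every loaded slat is fully lowered, the conservation rule cannot hold;
    this is reported and the load is kept on the least-lowered slats.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.shape != (N_HOPB,):
        raise ValueError(f"need {N_HOPB} heights")
    f = np.maximum(0.0, 1.0 + heights / MAX_HEIGHT_MM)  # per-slat attenuation
    col_factor = _COL_TO_SLAT @ f  # (64,)
    attenuated = frame.values * col_factor[None, :]
    total = frame.values.sum()
    kept = attenuated.sum()
    if total == 0:
        return PressureFrame(frame.values.copy(), frame.timestamp_period)
    if kept <= 0:
        warnings.warn("all loaded slats fully lowered; load conservation "
                      "impossible — keeping load on the least-lowered slats")
        best = np.isclose(heights, heights.max())
        col_factor = _COL_TO_SLAT @ best.astype(float)
        attenuated = frame.values * col_factor[None, :]
        kept = attenuated.sum()
        if kept <= 0:
            return PressureFrame(frame.values.copy(), frame.timestamp_period)
    return PressureFrame(attenuated * (total / kept), frame.timestamp_period)


class BedSimulator:
    """Holds the trained classifier, fuzzy engine and calibration, and runs
    one full control cycle per 80 s period."""

    def __init__(
        self,
        classifier: ConvLSTMClassifier | None,
        engine: FuzzyEngine,
        stats: CalibrationStats,
        risk: RiskConfig = RiskConfig(),
        gain: float = DEFAULT_GAIN_MM,
        contact_floor: float = 1e-6,
    ) -> None:
        self.classifier = classifier
        self.engine = engine
        self.stats = stats
        self.risk = risk
        self.gain = gain
        self.contact_floor = contact_floor
        self._window: list[np.ndarray] = []
        self.log: list[dict] = []

    def _classify(self, grid: np.ndarray) -> int:
        if self.classifier is None:
            raise ValueError("no trained classifier attached")
        T = self.classifier.config.window_length
        self._window.append(grid)
        self._window = self._window[-T:]
        padded = ([self._window[0]] * (T - len(self._window))) + self._window
        return int(self.classifier.predict(np.stack(padded)))

    def _update_levels(self, state: BedState, heats: np.ndarray,
                       posture_changed: bool) -> HoPBLevels:
        levels = assign_levels(heats, self.stats)
        contact = heats > self.contact_floor
        if posture_changed:
            state.dwell = np.zeros(N_HOPB, dtype=int)
        state.dwell = np.where(contact, state.dwell + 1, 0)
        time_level = np.array([time_to_level(int(k)) if c else 0
                               for k, c in zip(state.dwell, contact)])
        time_level[contact & (time_level == 0)] = 1
        phase = level_to_phase(levels)
        return HoPBLevels(heat=heats, level=levels, phase=phase,
                          time_level=time_level)

    def step(self, state: BedState, frame: PressureFrame
             ) -> tuple[BedState, ControlOutput]:
        """One full cycle: pool -> classify -> levels/time -> infer -> apply.

        A zero frame means no occupant: the posture falls back to "none",
        settings are all zero and the heights stay put.
        """
        grid = pool_frame(frame)
        heats = hopb_heat(grid)
        record: dict = {"period": state.period}
        if frame.values.sum() <= self.contact_floor:
            state.posture_history.append(-1)
            state.dwell[:] = 0
            control = ControlOutput(np.zeros(N_HOPB))
            state.levels = None
            record.update(stage="no_occupant", posture=None,
                          settings=control.settings.copy(),
                          heights=state.heights.copy(), immediate_reposition=False)
            self.log.append(record)
            state.period += 1
            return state, control

        try:
            posture = self._classify(grid.values)
        except Exception as exc:  # tag the failing stage for the operator
            raise RuntimeError(f"classification stage failed: {exc}") from exc
        posture_changed = (state.posture is not None and state.posture != -1
                           and posture != state.posture)
        state.posture_history.append(posture)
        try:
            levels = self._update_levels(state, heats, posture_changed)
            state.levels = levels
        except Exception as exc:
            raise RuntimeError(f"risk-scoring stage failed: {exc}") from exc
        try:
            control = self.engine.infer(levels, posture)
        except Exception as exc:
            raise RuntimeError(f"fuzzy-inference stage failed: {exc}") from exc
        apply_settings(state, control, self.gain)
        immediate = bool(np.any(levels.phase >= self.risk.immediate_reposition_phase))
        record.update(stage="ok", posture=posture,
                      levels=levels.level.copy(), phases=levels.phase.copy(),
                      time_levels=levels.time_level.copy(),
                      settings=control.settings.copy(),
                      heights=state.heights.copy(),
                      immediate_reposition=immediate)
        self.log.append(record)
        state.period += 1
        return state, control

    def run(self, frames: list[PressureFrame], state: BedState | None = None,
            redistribute: bool = True) -> BedState:
        """Run the closed loop over a frame sequence, optionally feeding each
        period's frame through the pressure-redistribution model first."""
        state = state or BedState()
        for frame in frames:
            if redistribute:
                frame = redistribute_pressure(frame, state.heights)
            state, _ = self.step(state, frame)
        return state

    def guidance_report(self, state: BedState) -> GuidanceReport:
        """Assemble the caregiver guidance from the current state."""
        if state.period == 0 or not self.log:
            raise ValueError("no completed control step to report on")
        if state.posture is None or state.posture == -1 or state.levels is None:
            return GuidanceReport("no occupant detected", "none", [], [], [])
        levels = state.levels
        posture = state.posture
        contact = [i + 1 for i in range(N_HOPB) if levels.level[i] > 0]
        areas, phases = [], []
        for i in range(N_HOPB):
            if levels.phase[i] >= 1:
                region = region_of_slat(posture, i + 1) or "general contact"
                areas.append((i + 1, region))
                phases.append(int(levels.phase[i]))
        if any(p >= self.risk.immediate_reposition_phase for p in phases):
            recommendation = ("immediate reposition: turn the patient off the "
                              "affected area")
            worst = max(phases)
        elif phases and max(phases) >= 2:
            recommendation = "schedule a position change this shift"
        else:
            recommendation = "maintain position"
        return GuidanceReport(
            recommended_position_change=recommendation,
            current_posture=PostureLabel(posture).name,
            ulcer_areas=areas,
            ulcer_phases=phases,
            contact_hopbs=contact,
        )
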