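"""Synthetic body-pressure frame generator.

Emulates a pressure-sensor mattress with a 32x64 grid: 64 columns run along
the bed's long axis (column 0 = head end) and 32 rows run across its width.
A lying body is rendered as a sum of anisotropic Gaussian contact blobs
(head, shoulders, torso, pelvis, thighs, heels ...) placed from a per-posture
template, scaled by simple body parameters, with additive truncated-at-zero
sensor noise.  Ten posture templates mirror the ten classes used for in-bed
posture recognition on public pressure-mat data (supine variants, left/right
lateral, left/right fetus).

Pressure is in arbitrary units, monotone in mmHg; templates are calibrated so
the pelvic blob of an average body exceeds a nominal 32-unit (32 mmHg
equivalent) ischemia threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_ROWS = 32  #: sensors across the bed width
N_COLS = 64  #: sensors along the head-to-foot axis

#: Posture class names, index 0-9.
POSTURE_NAMES = (
    "Supine",
    "Right",
    "Left",
    "Supine wide",
    "Supine straight",
    "supine raised",
    "supine right raised",
    "supine left raised",
    "right fetus",
    "left fetus",
)

_ROW_MID = (N_ROWS - 1) / 2.0  # 15.5, the bed's lateral midline
_HEAD_COL = 4.0  # anchor column for height scaling


@dataclass(frozen=True)
class PostureLabel:
    """A lying-posture class: integer index 0-9 with its canonical name."""

    index: int
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 9:
            raise ValueError(f"posture index must be 0-9, got {self.index}")
        expected = POSTURE_NAMES[self.index]
        if self.name == "":
            object.__setattr__(self, "name", expected)
        elif self.name != expected:
            raise ValueError(
                f"posture name {self.name!r} does not match index {self.index} "
                f"({expected!r})"
            )

    @classmethod
    def from_name(cls, name: str) -> "PostureLabel":
        try:
            return cls(POSTURE_NAMES.index(name))
        except ValueError:
            raise ValueError(f"unknown posture name {name!r}") from None


@dataclass(frozen=True)
class BodyParams:
    """Per-subject body variability.

    height_scale stretches the template along the bed's long axis,
    weight_scale scales contact pressures, lateral_offset shifts the body
    across the bed width (in sensor pitches), noise_sd is the standard
    deviation of the additive sensor noise (pressure units).
    """

    height_scale: float = 1.0
    weight_scale: float = 1.0
    lateral_offset: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.height_scale <= 0:
            raise ValueError("height_scale must be strictly positive")
        if self.weight_scale < 0:
            raise ValueError("weight_scale must be non-negative")
        if abs(self.lateral_offset) > 10:
            raise ValueError("lateral_offset would push the body off the mat")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PressureFrame:
    """One 32x64 non-negative pressure snapshot at an 80 s control period."""

    values: np.ndarray
    timestamp_period: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ROWS, N_COLS):
            raise ValueError(
                f"frame must be {N_ROWS}x{N_COLS}, got {self.values.shape}"
            )
        if np.all(np.isnan(self.values)):
            raise ValueError("frame is all-NaN")
        if np.nanmin(self.values) < 0:
            raise ValueError("pressure values must be non-negative")

    @property
    def total_load(self) -> float:
        return float(self.values.sum())


# One contact blob: (row_center, col_center, row_sigma, col_sigma,
# angle_degrees, peak_pressure).  Rows are symmetric about 15.5 for the
# supine family so that those templates are laterally symmetric.
_Blob = tuple[float, float, float, float, float, float]


def _mirror(parts: list[_Blob]) -> list[_Blob]:
    """Reflect a template across the bed's lateral midline (row axis)."""
    return [
        (2 * _ROW_MID - r, c, sr, sc, -ang, pk) for (r, c, sr, sc, ang, pk) in parts
    ]


def _supine_parts(
    shoulder_spread: float = 4.5,
    thigh_spread: float = 2.5,
    heel_spread: float = 2.0,
    arm_blobs: bool = False,
) -> list[_Blob]:
    m = _ROW_MID
    parts: list[_Blob] = [
        (m, 6.0, 2.2, 2.6, 0.0, 30.0),  # occiput
        (m - shoulder_spread, 15.0, 2.5, 3.0, 0.0, 40.0),
        (m + shoulder_spread, 15.0, 2.5, 3.0, 0.0, 40.0),
        (m, 22.0, 4.0, 5.0, 0.0, 28.0),  # thoracic/lumbar
        (m, 33.0, 3.5, 4.0, 0.0, 60.0),  # sacrum/pelvis
        (m - thigh_spread, 42.0, 2.0, 4.5, 0.0, 22.0),
        (m + thigh_spread, 42.0, 2.0, 4.5, 0.0, 22.0),
        (m - heel_spread, 57.0, 1.2, 1.8, 0.0, 35.0),
        (m + heel_spread, 57.0, 1.2, 1.8, 0.0, 35.0),
    ]
    if arm_blobs:
        parts += [
            (m - 9.0, 25.0, 1.5, 4.0, 0.0, 15.0),
            (m + 9.0, 25.0, 1.5, 4.0, 0.0, 15.0),
        ]
    return parts


def _right_lateral_parts() -> list[_Blob]:
    # Lying on the right side: load concentrates on a narrow contact line
    # (shoulder, greater trochanter), with a slight lateral drift toward
    # the knees/feet.
    return [
        (14.0, 6.0, 1.8, 2.4, 0.0, 32.0),  # side of head
        (14.5, 15.0, 1.8, 2.6, 0.0, 55.0),  # shoulder
        (15.0, 23.0, 2.2, 4.5, 0.0, 30.0),  # ribcage
        (15.5, 33.0, 2.0, 3.0, 0.0, 62.0),  # trochanter
        (17.5, 44.0, 1.8, 2.8, 10.0, 30.0),  # knees
        (18.5, 55.0, 1.3, 2.0, 0.0, 30.0),  # ankle/foot
    ]


def _supine_raised_parts() -> list[_Blob]:
    # Backrest raised: head barely touches, load shifts onto the sacrum.
    m = _ROW_MID
    return [
        (m, 8.0, 2.0, 2.2, 0.0, 6.0),
        (m - 4.0, 17.0, 2.2, 2.6, 0.0, 20.0),
        (m + 4.0, 17.0, 2.2, 2.6, 0.0, 20.0),
        (m, 25.0, 3.5, 4.0, 0.0, 24.0),
        (m, 31.0, 3.5, 4.0, 0.0, 75.0),  # sacrum takes the trunk weight
        (m - 2.5, 42.0, 2.0, 4.0, 0.0, 24.0),
        (m + 2.5, 42.0, 2.0, 4.0, 0.0, 24.0),
        (m - 2.0, 56.0, 1.2, 1.8, 0.0, 30.0),
        (m + 2.0, 56.0, 1.2, 1.8, 0.0, 30.0),
    ]


def _supine_right_raised_parts() -> list[_Blob]:
    # Right half of the backrest raised: trunk load rolls toward low rows.
    shifted: list[_Blob] = []
    for r, c, sr, sc, ang, pk in _supine_parts():
        w = 1.25 if r < _ROW_MID else 0.75  # load shifts off the raised side
        shifted.append((r - 2.5, c, sr, sc, ang, pk * w))
    return shifted


def _right_fetus_parts() -> list[_Blob]:
    # Curled on the right side: shortened body, knees drawn toward the chest.
    return [
        (13.0, 8.0, 1.8, 2.2, 0.0, 34.0),
        (13.5, 16.0, 1.8, 2.6, 0.0, 50.0),  # shoulder
        (14.5, 24.0, 2.2, 3.5, 0.0, 28.0),  # curled trunk
        (15.5, 31.0, 2.0, 2.8, 0.0, 58.0),  # hip
        (19.0, 37.0, 2.0, 2.6, -20.0, 36.0),  # knees drawn up
        (20.0, 43.0, 1.4, 2.0, 0.0, 24.0),  # feet tucked
    ]


def _build_templates() -> dict[int, list[_Blob]]:
    right = _right_lateral_parts()
    right_raised = _supine_right_raised_parts()
    right_fetus = _right_fetus_parts()
    return {
        0: _supine_parts(),
        1: right,
        2: _mirror(right),
        3: _supine_parts(shoulder_spread=6.0, thigh_spread=4.0,
                         heel_spread=5.5, arm_blobs=True),
        4: _supine_parts(shoulder_spread=3.5, thigh_spread=1.3,
                         heel_spread=1.0),
        5: _supine_raised_parts(),
        6: right_raised,
        7: _mirror(right_raised),
        8: right_fetus,
        9: _mirror(right_fetus),
    }


TEMPLATES: dict[int, list[_Blob]] = _build_templates()


def _render_template(posture_index: int, body: BodyParams) -> np.ndarray:
    rows = np.arange(N_ROWS, dtype=float)[:, None]
    cols = np.arange(N_COLS, dtype=float)[None, :]
    frame = np.zeros((N_ROWS, N_COLS))
    for r0, c0, sr, sc, ang, peak in TEMPLATES[posture_index]:
        r0 = r0 + body.lateral_offset
        c0 = _HEAD_COL + (c0 - _HEAD_COL) * body.height_scale
        sc = sc * body.height_scale
        theta = np.deg2rad(ang)
        dr, dc = rows - r0, cols - c0
        u = np.cos(theta) * dr - np.sin(theta) * dc
        v = np.sin(theta) * dr + np.cos(theta) * dc
        frame += peak * body.weight_scale * np.exp(
            -0.5 * ((u / sr) ** 2 + (v / sc) ** 2)
        )
    return frame


def generate_frame(
    posture: PostureLabel | int,
    body: BodyParams | None = None,
    seed: int = 0,
    timestamp_period: int = 0,
) -> PressureFrame:
    """Render one pressure frame for a posture and body, with seeded noise.

    The frame is the posture template's blob sum scaled by the body
    parameters plus Gaussian sensor noise truncated at zero; the same
    (posture, body, seed) always yields a bit-identical frame.
    """
    idx = posture.index if isinstance(posture, PostureLabel) else int(posture)
    if not 0 <= idx <= 9:
        raise ValueError(f"unknown posture index {idx}")
    body = body or BodyParams()
    clean = _render_template(idx, body)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, body.noise_sd, clean.shape) if body.noise_sd > 0 else clean
    return PressureFrame(np.maximum(noisy, 0.0), timestamp_period)


def generate_sequence(
    schedule: list[tuple[PostureLabel | int, int]],
    body: BodyParams | None = None,
    seed: int = 0,
) -> list[PressureFrame]:
    """Render one frame per 80 s period following a posture schedule.

    ``schedule`` is a list of (posture, n_periods) segments; posture changes
    occur exactly at segment boundaries and every frame gets independent
    noise drawn from a single seeded stream.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    body = body or BodyParams()
    seq_rng = np.random.default_rng(seed)
    frames: list[PressureFrame] = []
    period = 0
    for posture, n_periods in schedule:
        if n_periods < 1:
            raise ValueError("each schedule segment needs n_periods >= 1")
        idx = posture.index if isinstance(posture, PostureLabel) else int(posture)
        clean = _render_template(idx, body)
        for _ in range(n_periods):
            noisy = (
                clean + seq_rng.normal(0.0, body.noise_sd, clean.shape)
                if body.noise_sd > 0
                else clean
            )
            frames.append(PressureFrame(np.maximum(noisy, 0.0), period))
            period += 1
    return frames


@dataclass
class FrameDataset:
    """A labeled, class-balanced collection of synthetic frames."""

    frames: list[PressureFrame]
    labels: np.ndarray  # posture index per frame
    subjects: np.ndarray  # synthetic subject id per frame
    bodies: list[BodyParams] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def _draw_body(rng: np.random.Generator) -> BodyParams:
    # Uniform subject variability standing in for a small multi-subject cohort.
    return BodyParams(
        height_scale=rng.uniform(0.8, 1.2),
        weight_scale=rng.uniform(0.8, 1.2),
        lateral_offset=rng.uniform(-3.0, 3.0),
        noise_sd=rng.uniform(0.5, 2.0),
    )


def generate_dataset(n_per_class: int, seed: int = 0) -> FrameDataset:
    """Generate a class-balanced labeled dataset, 10 x ``n_per_class`` frames.

    Body parameters are drawn per sample from uniform ranges
    (height/weight scales 0.8-1.2, lateral offset +/-3 pitches, noise sd
    0.5-2.0); the same seed reproduces the dataset bit-identically.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    frames, labels, subjects, bodies = [], [], [], []
    for cls in range(10):
        for i in range(n_per_class):
            body = _draw_body(rng)
            frame_seed = int(rng.integers(0, 2**31 - 1))
            frames.append(generate_frame(cls, body, frame_seed))
            labels.append(cls)
            subjects.append(i)
            bodies.append(body)
    return FrameDataset(frames, np.array(labels), np.array(subjects), bodies)
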