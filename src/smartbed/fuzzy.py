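"""Mamdani fuzzy controller for the 20 bed slats.

Classic Mamdani pipeline: crisp inputs are fuzzified against triangular
membership functions, AND antecedents combine by minimum, each fired rule
truncates (min-implication) its consequent set, fired consequents aggregate
by pointwise maximum, and the aggregated set defuzzifies by centre of
gravity (COG) on a dense grid.  The rule base is the full Cartesian product
20 slats x 10 postures x 8 time levels x 5 ulcer phases = 8000 AND rules;
slat and posture are crisp (singleton) selectors, so each inference touches
the 40 rules of one (slat, posture) cell.  Rules that never fire on a
calibration set can be purged without changing any calibration output.

Consequents come from a deterministic policy over a per-posture body-region
map: slats under pressure-prone regions (sacrum, heels, shoulders...) descend
as ulcer phase and dwell time grow; neighbouring support slats rise to take
over load; everything else holds still until phase 4+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .preprocess import MAX_LEVEL, MAX_TIME_LEVEL, N_HOPB, HoPBLevels
from .synthetic import POSTURE_NAMES, PostureLabel

OUTPUT_UNIVERSE = (-2.0, 2.0)
DEFAULT_RESOLUTION = 0.0005

#: Consequent labels, most negative (deep descent) to most positive.
CONSEQUENT_NAMES = (
    "Large Descent",
    "Slight Descent",
    "Not Moving",
    "Slight Rise",
    "Large Rise",
)


@dataclass(frozen=True)
class MembershipFunction:
    """A triangular fuzzy set (a, b, c) on a closed universe.

    mu rises linearly from 0 at ``a`` to 1 at ``b`` and falls back to 0 at
    ``c``; a == b or b == c gives a shoulder (one-sided) set.  Inputs outside
    the universe are clamped to its bounds before evaluation.
    """

    name: str
    a: float
    b: float
    c: float
    universe: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.a <= self.b <= self.c:
            raise ValueError(f"need a <= b <= c, got {(self.a, self.b, self.c)}")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.clip(x, *self.universe)
        a, b, c = self.a, self.b, self.c
        left = np.where(a == b, 1.0, (x - a) / (b - a if b > a else 1.0))
        right = np.where(b == c, 1.0, (c - x) / (c - b if c > b else 1.0))
        mu = np.clip(np.minimum(left, right), 0.0, 1.0)
        return float(mu) if np.isscalar(x) or np.ndim(x) == 0 else mu


def _triangles(
    centers: Sequence[float], half_width: float, names: Sequence[str],
    universe: tuple[float, float],
) -> list[MembershipFunction]:
    return [
        MembershipFunction(n, c - half_width, c, c + half_width, universe)
        for n, c in zip(names, centers)
    ]


@dataclass(frozen=True)
class FuzzyVariable:
    """A named linguistic variable with its member sets."""

    name: str
    universe: tuple[float, float]
    sets: tuple[MembershipFunction, ...]

    def __getitem__(self, set_name: str) -> MembershipFunction:
        for mf in self.sets:
            if mf.name == set_name:
                return mf
        raise KeyError(f"{self.name} has no set {set_name!r}")


def default_variables() -> dict[str, FuzzyVariable]:
    """The controller's variables with fixed triangular memberships.

    Time levels 1-8 get unit-spaced triangles of half-width 2 (50% overlap);
    ulcer phases 1-5 get triangles of half-width 4 centred at the mid-levels
    2.5, 6.5, 10.5, 14.5, 18.5 of the width-4 level bins; the actuation
    output on [-2, 2] gets five symmetric triangles whose centroids set the
    magnitude of single-rule movements.
    """
    time_sets = _triangles(
        centers=range(1, MAX_TIME_LEVEL + 1), half_width=2.0,
        names=[f"Time{k}" for k in range(1, MAX_TIME_LEVEL + 1)],
        universe=(1.0, float(MAX_TIME_LEVEL)),
    )
    phase_sets = _triangles(
        centers=[2.5, 6.5, 10.5, 14.5, 18.5], half_width=4.0,
        names=[f"Phase {k}" for k in range(1, 6)],
        universe=(0.0, float(MAX_LEVEL)),
    )
    out_centers = {"Large Descent": -1.5, "Slight Descent": -0.6, "Not Moving": 0.0,
                   "Slight Rise": 0.6, "Large Rise": 1.5}
    out_half = {"Large Descent": 0.5, "Slight Descent": 0.6, "Not Moving": 0.6,
                "Slight Rise": 0.6, "Large Rise": 0.5}
    out_sets = [
        MembershipFunction(n, out_centers[n] - out_half[n], out_centers[n],
                           out_centers[n] + out_half[n], OUTPUT_UNIVERSE)
        for n in CONSEQUENT_NAMES
    ]
    return {
        "TimeLevel": FuzzyVariable("TimeLevel", (1.0, float(MAX_TIME_LEVEL)),
                                   tuple(time_sets)),
        "UlcerLevel": FuzzyVariable("UlcerLevel", (0.0, float(MAX_LEVEL)),
                                    tuple(phase_sets)),
        "HoPBControl": FuzzyVariable("HoPBControl", OUTPUT_UNIVERSE, tuple(out_sets)),
    }


@dataclass(frozen=True)
class FuzzyRule:
    """One AND rule: IF HoPB is h AND Decubitus is p AND Time level is t AND
    Ulcer Level is Phase q THEN HoPB Control is <consequent>.

    ``hopb`` is 1-based (1-20), ``posture`` 0-based (0-9), ``time_set`` and
    ``phase_set`` name fuzzy sets of TimeLevel / UlcerLevel.
    """

    hopb: int
    posture: int
    time_set: str
    phase_set: str
    consequent: str

    def __post_init__(self) -> None:
        if not 1 <= self.hopb <= N_HOPB:
            raise ValueError(f"hopb must be 1-{N_HOPB}")
        if not 0 <= self.posture <= 9:
            raise ValueError("posture must be 0-9")
        if self.consequent not in CONSEQUENT_NAMES:
            raise ValueError(f"unknown consequent {self.consequent!r}")

    def to_line(self) -> str:
        return (
            f"HoPB{self.hopb} & {POSTURE_NAMES[self.posture]} & {self.time_set}"
            f" & {self.phase_set} -> {self.consequent.replace(' ', '')}"
        )

    @classmethod
    def from_line(cls, line: str) -> "FuzzyRule":
        lhs, _, rhs = line.partition("->")
        parts = [p.strip() for p in lhs.split("&")]
        if len(parts) != 4 or not rhs.strip():
            raise ValueError(f"cannot parse rule line: {line!r}")
        hopb = int(parts[0].removeprefix("HoPB"))
        posture = POSTURE_NAMES.index(parts[1])
        cons = rhs.strip()
        for name in CONSEQUENT_NAMES:
            if name.replace(" ", "") == cons or name == cons:
                cons = name
                break
        return cls(hopb, posture, parts[2], parts[3], cons)


@dataclass
class ControlOutput:
    """Crisp movement settings for the 20 slats, in output-universe units
    (positive = rise, negative = descent; 1 unit = 20 mm at default gain)."""

    settings: np.ndarray

    def __post_init__(self) -> None:
        self.settings = np.asarray(self.settings, dtype=float)
        if self.settings.shape != (N_HOPB,):
            raise ValueError(f"need {N_HOPB} settings")
        if not np.all(np.isfinite(self.settings)):
            raise ValueError("settings must be finite")
        lo, hi = OUTPUT_UNIVERSE
        if self.settings.min() < lo or self.settings.max() > hi:
            raise ValueError(f"settings must lie in {OUTPUT_UNIVERSE}")


@dataclass(frozen=True)
class RiskConfig:
    """Clinical thresholds: the sustained-pressure ceiling (32 mmHg
    equivalent) and the ulcer phase from which repositioning is immediate."""

    pressure_threshold: float = 32.0
    immediate_reposition_phase: int = 3

    def __post_init__(self) -> None:
        if self.pressure_threshold <= 0:
            raise ValueError("pressure_threshold must be positive")


# --- body-region maps -------------------------------------------------------

#: Default pressure-prone regions per posture: region name -> 1-based slats.
#: Supine assignments follow the bed's clinical narrative (slat 4 cervical,
#: 5-6 shoulders, 7-8 spine, 9-11 pelvis, 16 calf, 18 heel); lateral and
#: fetal maps place the analogous bony prominences.
DEFAULT_REGION_MAPS: dict[int, dict[str, tuple[int, ...]]] = {
    0: {"cervical": (4,), "shoulders": (5, 6), "spine": (7, 8),
        "pelvis": (9, 10, 11), "calf": (16,), "heel": (18,)},
    1: {"head": (3,), "shoulder": (5, 6), "trochanter": (9, 10, 11),
        "knee": (14,), "ankle": (17,)},
    2: {"head": (3,), "shoulder": (5, 6), "trochanter": (9, 10, 11),
        "knee": (14,), "ankle": (17,)},
    3: {"cervical": (4,), "shoulders": (5, 6), "spine": (7, 8),
        "pelvis": (9, 10, 11), "calf": (15, 16), "heel": (18, 19)},
    4: {"cervical": (4,), "shoulders": (5, 6), "spine": (7, 8),
        "pelvis": (9, 10, 11), "calf": (16,), "heel": (18,)},
    5: {"shoulders": (5, 6), "sacrum": (9, 10, 11), "heel": (18,)},
    6: {"cervical": (4,), "shoulders": (5, 6), "pelvis": (9, 10, 11),
        "heel": (18,)},
    7: {"cervical": (4,), "shoulders": (5, 6), "pelvis": (9, 10, 11),
        "heel": (18,)},
    8: {"head": (3,), "shoulder": (5, 6), "hip": (9, 10), "knee": (12, 13)},
    9: {"head": (3,), "shoulder": (5, 6), "hip": (9, 10), "knee": (12, 13)},
}


def prone_slats(posture: int, region_map: Mapping[int, Mapping[str, tuple[int, ...]]]
                | None = None) -> set[int]:
    rm = (region_map or DEFAULT_REGION_MAPS)[posture]
    return {h for slats in rm.values() for h in slats}


def region_of_slat(posture: int, hopb: int,
                   region_map: Mapping[int, Mapping[str, tuple[int, ...]]]
                   | None = None) -> str | None:
    for region, slats in (region_map or DEFAULT_REGION_MAPS)[posture].items():
        if hopb in slats:
            return region
    return None


def _policy_consequent(hopb: int, posture: int, time_k: int, phase: int,
                       prone: set[int]) -> str:
    """Deterministic consequent policy for one rule cell.

    Prone slats hold still at low phase, descend at phase 4+ and escalate to
    a large descent when phase 5 persists; support slats (within 2 of a prone
    slat) rise at low phase once dwell time builds, so load can transfer;
    remaining slats hold still through phase 3 and descend beyond.
    Settings are non-increasing in phase at fixed slat/posture/time.
    """
    is_prone = hopb in prone
    is_support = not is_prone and any(abs(hopb - p) <= 2 for p in prone)
    if phase >= 5:
        return "Large Descent" if time_k >= 5 else "Slight Descent"
    if phase == 4:
        return "Slight Descent"
    if phase == 3:
        return "Slight Descent" if is_prone and time_k >= 5 else "Not Moving"
    # phase 1-2: unloaded-enough slats may rise to take over load
    if is_support:
        if phase == 1 and time_k >= 3:
            return "Slight Rise"
        if phase == 2 and time_k >= 5:
            return "Slight Rise"
    return "Not Moving"


def build_rule_base(
    region_map: Mapping[int, Mapping[str, tuple[int, ...]]] | None = None,
    policy: Callable[[int, int, int, int, set[int]], str] | None = None,
) -> list[FuzzyRule]:
    """Enumerate the full 20 x 10 x 8 x 5 = 8000-rule Cartesian base.

    Consequents come from the deterministic region policy; duplicate
    antecedent combinations are rejected.
    """
    policy = policy or _policy_consequent
    rules: list[FuzzyRule] = []
    seen: set[tuple[int, int, int, int]] = set()
    for posture in range(10):
        prone = prone_slats(posture, region_map)
        for hopb in range(1, N_HOPB + 1):
            for t in range(1, MAX_TIME_LEVEL + 1):
                for q in range(1, 6):
                    key = (hopb, posture, t, q)
                    if key in seen:
                        raise ValueError(f"duplicate rule antecedents {key}")
                    seen.add(key)
                    rules.append(FuzzyRule(
                        hopb, posture, f"Time{t}", f"Phase {q}",
                        policy(hopb, posture, t, q, prone),
                    ))
    return rules


def save_rules(rules: Iterable[FuzzyRule], path: str) -> None:
    with open(path, "w") as fh:
        for r in rules:
            fh.write(r.to_line() + "\n")


def load_rules(path: str) -> list[FuzzyRule]:
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                rules.append(FuzzyRule.from_line(line))
    return rules


# --- inference --------------------------------------------------------------


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Degree to which crisp ``x`` belongs to the set (clamped to universe)."""
    return float(mf(x))


def fire_rule(rule: FuzzyRule, inputs: Mapping[str, float],
              variables: Mapping[str, FuzzyVariable]) -> float:
    """Firing strength of an AND rule: the minimum antecedent degree.

    ``inputs`` must provide crisp values for HoPB, Decubitus, TimeLevel and
    UlcerLevel; HoPB/Decubitus are crisp selectors (degree 1 on match, else
    0).  The rule is "fired" iff the returned strength is > 0.
    """
    for key in ("HoPB", "Decubitus", "TimeLevel", "UlcerLevel"):
        if key not in inputs:
            raise KeyError(f"missing crisp input {key!r}")
    if int(inputs["HoPB"]) != rule.hopb or int(inputs["Decubitus"]) != rule.posture:
        return 0.0
    mu_t = variables["TimeLevel"][rule.time_set](inputs["TimeLevel"])
    mu_q = variables["UlcerLevel"][rule.phase_set](inputs["UlcerLevel"])
    return float(min(1.0, 1.0, mu_t, mu_q))


def aggregate(
    fired: Sequence[tuple[float, MembershipFunction]],
) -> Callable[[np.ndarray], np.ndarray]:
    """Mamdani aggregation: mu(y) = max_k min(strength_k, mu_Bk(y)).

    An empty list aggregates to the identically-zero function.
    """

    def mu(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        out = np.zeros_like(y)
        for strength, mf in fired:
            np.maximum(out, np.minimum(strength, mf(y)), out=out)
        return out

    return mu


def defuzzify_cog(
    mu: Callable[[np.ndarray], np.ndarray],
    resolution: float = DEFAULT_RESOLUTION,
    universe: tuple[float, float] = OUTPUT_UNIVERSE,
) -> float:
    """Centre-of-gravity defuzzification by trapezoid quadrature.

    COG = int y mu(y) dy / int mu(y) dy on a uniform grid of the given step;
    a zero-area aggregate defuzzifies to 0.0 (fail-safe: not moving).
    """
    lo, hi = universe
    n = int(round((hi - lo) / resolution)) + 1
    y = np.linspace(lo, hi, n)
    m = np.asarray(mu(y), dtype=float)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("membership values must be finite")
    area = np.trapezoid(m, y)
    if area <= 0.0:
        return 0.0
    return float(np.trapezoid(y * m, y) / area)


class FuzzyEngine:
    """Rule base + memberships bundled for per-slat inference."""

    def __init__(
        self,
        rules: Sequence[FuzzyRule] | None = None,
        variables: Mapping[str, FuzzyVariable] | None = None,
        resolution: float = DEFAULT_RESOLUTION,
    ) -> None:
        self.variables = dict(variables or default_variables())
        self.rules = list(rules if rules is not None else build_rule_base())
        self.resolution = resolution
        self._index: dict[tuple[int, int], list[FuzzyRule]] = {}
        seen: set[tuple[int, int, str, str]] = set()
        for r in self.rules:
            key = (r.hopb, r.posture, r.time_set, r.phase_set)
            if key in seen:
                raise ValueError(f"duplicate rule antecedents {key}")
            seen.add(key)
            self._index.setdefault((r.hopb, r.posture), []).append(r)

    def infer_slat(self, hopb: int, posture: int, time_level: float,
                   ulcer_level: float) -> float:
        """One crisp setting for one slat via fire -> truncate -> max -> COG."""
        out_var = self.variables["HoPBControl"]
        inputs = {"HoPB": hopb, "Decubitus": posture,
                  "TimeLevel": time_level, "UlcerLevel": ulcer_level}
        fired = []
        for rule in self._index.get((hopb, posture), []):
            s = fire_rule(rule, inputs, self.variables)
            if s > 0.0:
                fired.append((s, out_var[rule.consequent]))
        return defuzzify_cog(aggregate(fired), self.resolution)

    def infer(self, levels: HoPBLevels, posture: PostureLabel | int) -> ControlOutput:
        """Crisp settings for all 20 slats.

        Slats with no contact (level 0) are held still without consulting the
        rule base; the rest run the full Mamdani pipeline on their
        (time level, ulcer level) inputs.
        """
        p = posture.index if isinstance(posture, PostureLabel) else int(posture)
        if not 0 <= p <= 9:
            raise ValueError("invalid posture")
        settings = np.zeros(N_HOPB)
        for i in range(N_HOPB):
            if levels.level[i] == 0:
                continue
            settings[i] = self.infer_slat(
                i + 1, p, float(levels.time_level[i]), float(levels.level[i])
            )
        return ControlOutput(settings)

    def purge_rules(
        self,
        calibration_inputs: Sequence[tuple[int, int, float, float]],
        epsilon: float = 0.0,
    ) -> list[FuzzyRule]:
        """Drop rules whose max firing strength over a calibration set of
        (hopb, posture, time_level, ulcer_level) tuples is <= epsilon.

        Aggregation is a max over fired rules, so removing never-fired rules
        leaves every calibration inference unchanged.
        """
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        max_strength: dict[int, float] = {}
        for hopb, posture, t, q in calibration_inputs:
            inputs = {"HoPB": hopb, "Decubitus": posture,
                      "TimeLevel": t, "UlcerLevel": q}
            for rule in self._index.get((int(hopb), int(posture)), []):
                s = fire_rule(rule, inputs, self.variables)
                key = id(rule)
                if s > max_strength.get(key, 0.0):
                    max_strength[key] = s
        return [r for r in self.rules if max_strength.get(id(r), 0.0) > epsilon]
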