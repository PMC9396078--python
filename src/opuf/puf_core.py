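"""Personal utility functions (PUFs) from compositional responses.

A respondent's value set is built from three separately elicited
components:

1. *Level ratings* — how much health remains at each severity level, on
   a 0-100 scale shared across dimensions (100 = no problems, 0 =
   extreme problems).  Converted to disutilities ``l = 1 - rating/100``.
2. *Swing weights* — the relative importance of improving each dimension
   from its worst to its best level, on a 0-100 scale with the most
   important dimension fixed at 100 as yardstick.  Normalised to sum
   to 1.
3. *An anchor* — either the state judged equal to being dead
   (position-of-dead) or a visual-analogue rating of the worst state
   against dead (Dead-VAS).  Yields the anchoring factor ``a``, the
   respondent's utility range.

The outer product of disutilities and normalised weights gives the
scaled coefficient matrix ``M~``; dividing by the scaled disutility of
the equal-to-dead state (equivalently multiplying by ``a``) anchors it
onto the QALY scale where full health = 1 and dead = 0:

    V(h) = 1 - a * sum_i  l(h_i) * w_i

Everything is kept at full floating-point precision internally;
rounding (half-up, two decimals) is a display concern only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .descriptive_system import (
    DescriptiveSystem,
    HealthState,
    enumerate_states,
    parse_state,
)

__all__ = [
    "LevelRatings",
    "LevelDisutilities",
    "SwingWeights",
    "ScaledCoefficientMatrix",
    "Anchor",
    "PersonalValueSet",
    "ratings_to_disutilities",
    "normalize_weights",
    "build_matrix",
    "scaled_value",
    "anchoring_factor",
    "anchor_matrix",
    "rank_all_states",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for displayed values."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# level ratings and disutilities

@dataclass(frozen=True)
class LevelRatings:
    """Per-severity-level ratings on the 0-100 '% health remaining' scale.

    One shared set for all dimensions.  The endpoints are fixed by the
    task design: the best level ('no problems') is 100 and the worst
    ('extreme problems') is 0.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("need ratings for at least 2 levels")
        if vals[0] != 100.0 or vals[-1] != 0.0:
            raise ValueError(
                f"endpoint ratings must be 100 (best) and 0 (worst), got "
                f"{vals[0]} and {vals[-1]}"
            )
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError(f"ratings must lie in [0, 100]: {vals}")

    @property
    def is_monotone(self) -> bool:
        return all(a >= b for a, b in zip(self.values, self.values[1:]))


@dataclass(frozen=True)
class LevelDisutilities:
    """Disutility per severity level: 0 for 'no problems' up to 1 for 'extreme'."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError(
                f"endpoint disutilities must be 0 (best) and 1 (worst), got "
                f"{vals[0]} and {vals[-1]}"
            )


def ratings_to_disutilities(
    ratings: LevelRatings | Sequence[float], *, strict: bool = True
) -> LevelDisutilities:
    """Convert 0-100 level ratings to 0-1 disutilities, ``l = 1 - rating/100``.

    In strict mode non-monotone ratings (a worse level rated above a
    better one) raise; in lenient mode they are accepted with a warning,
    since the elicitation scale itself does not prevent them.
    """
    if not isinstance(ratings, LevelRatings):
        ratings = LevelRatings(tuple(ratings))
    if not ratings.is_monotone:
        if strict:
            raise ValueError(
                f"level ratings must be non-increasing best to worst: {ratings.values}"
            )
        warnings.warn(
            f"non-monotone level ratings accepted in lenient mode: {ratings.values}",
            stacklevel=2,
        )
    return LevelDisutilities(tuple(1.0 - v / 100.0 for v in ratings.values))


# ---------------------------------------------------------------------------
# swing weights

@dataclass(frozen=True)
class SwingWeights:
    """Raw 0-100 swing weights and their sum-to-1 normalisation."""

    raw: tuple[float, ...]
    normalized: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.normalized) - 1.0) > 1e-12:
            raise ValueError(f"normalized weights must sum to 1: {self.normalized}")


def normalize_weights(
    raw: Sequence[float], *, strict: bool = True
) -> SwingWeights:
    """Normalise raw swing weights to sum to 1 (full precision, no rounding).

    The swing-weighting task fixes the most important dimension at 100,
    so a valid response has max weight exactly 100.  Strict mode enforces
    this; lenient mode rescales by the maximum first (so the largest raw
    weight becomes the yardstick) before normalising.
    """
    raw = tuple(float(v) for v in raw)
    if not raw:
        raise ValueError("need at least one weight")
    if any(not 0.0 <= v <= 100.0 for v in raw):
        raise ValueError(f"raw weights must lie in [0, 100]: {raw}")
    mx = max(raw)
    if abs(mx - 100.0) > 1e-9:
        if strict:
            raise ValueError(
                f"no yardstick: the most important dimension must have raw weight "
                f"100, got max {mx}"
            )
        if mx == 0.0:
            raise ValueError("all-zero weight vector cannot be normalised")
        warnings.warn(
            f"missing yardstick 100 (max raw weight {mx}); rescaling by the maximum",
            stacklevel=2,
        )
        raw = tuple(v * 100.0 / mx for v in raw)
    total = sum(raw)
    norm = tuple(v / total for v in raw)
    return SwingWeights(raw=raw, normalized=norm)


# ---------------------------------------------------------------------------
# scaled coefficient matrix

@dataclass(frozen=True)
class ScaledCoefficientMatrix:
    """The 1-0 scaled level-by-dimension coefficient matrix ``M~``.

    ``values[level - 1, dim]`` is the scaled disutility increment of
    being at ``level`` on dimension ``dim``: the outer product
    ``l(level) * w(dim)``.  The top row (no problems) is all zeros and
    the bottom row (extreme problems) sums to 1, so ``1 - row sums``
    values states on a 1-0 scale.

    ``atol`` loosens the invariant checks; pass e.g. ``atol=0.02`` when
    reconstructing a matrix from display-rounded (2 d.p.) coefficients.
    """

    values: np.ndarray
    system: DescriptiveSystem
    atol: float = 1e-9

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n_levels = self.system.n_levels
        if len(set(n_levels)) != 1:
            raise ValueError(
                "shared level ratings require every dimension to have the same "
                f"number of levels, got {n_levels}"
            )
        expected = (n_levels[0], self.system.n_dimensions)
        if vals.shape != expected:
            raise ValueError(f"matrix shape {vals.shape} != {expected}")
        if np.any(np.abs(vals[0]) > self.atol):
            raise ValueError("the 'no problems' row must be all zeros")
        if abs(vals[-1].sum() - 1.0) > max(self.atol, 1e-9):
            raise ValueError(
                f"the 'extreme problems' row must sum to 1, got {vals[-1].sum()}"
            )
        if np.any(np.diff(vals, axis=0) < -self.atol):
            raise ValueError("columns must be non-decreasing from best to worst level")

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    def disutility(self, state: HealthState | str) -> float:
        """Scaled (0-1) disutility of a state: sum of its selected cells."""
        state = _as_state(state, self.system)
        idx = np.asarray(state.levels) - 1
        return float(self.values[idx, np.arange(self.system.n_dimensions)].sum())

    def disutilities(self, states: Sequence[HealthState]) -> np.ndarray:
        idx = np.array([s.levels for s in states]) - 1
        return self.values[idx, np.arange(self.system.n_dimensions)].sum(axis=1)


def build_matrix(
    l: LevelDisutilities, w: SwingWeights, system: DescriptiveSystem
) -> ScaledCoefficientMatrix:
    """Outer product of level disutilities and normalised weights."""
    lv = np.asarray(l.values)
    wv = np.asarray(w.normalized)
    if len(wv) != system.n_dimensions:
        raise ValueError(
            f"{len(wv)} weights for {system.n_dimensions} dimensions"
        )
    if len(lv) != system.n_levels[0]:
        raise ValueError(
            f"{len(lv)} level disutilities for {system.n_levels[0]} levels"
        )
    return ScaledCoefficientMatrix(values=np.outer(lv, wv), system=system)


def scaled_value(matrix: ScaledCoefficientMatrix, state: HealthState | str) -> float:
    """Value of a state on the 1-0 scale: ``1 - sum of selected cells``."""
    return 1.0 - matrix.disutility(state)


# ---------------------------------------------------------------------------
# anchoring

@dataclass(frozen=True)
class Anchor:
    """The elicited anchor: equal-to-dead state or Dead-VAS rating.

    ``kind`` is ``"position_of_dead"`` (with the state found equal to
    being dead) or ``"dead_vas"`` (with the worst state's 0-100 rating
    between dead = 0 and no problems = 100).
    """

    kind: Literal["position_of_dead", "dead_vas"]
    state: HealthState | None = None
    vas: float | None = None

    @classmethod
    def position_of_dead(cls, state: HealthState) -> "Anchor":
        return cls(kind="position_of_dead", state=state)

    @classmethod
    def dead_vas(cls, vas: float) -> "Anchor":
        vas = float(vas)
        if not 0.0 <= vas <= 100.0:
            raise ValueError(f"Dead-VAS value must lie in [0, 100], got {vas}")
        return cls(kind="dead_vas", vas=vas)


def anchoring_factor(anchor: Anchor, matrix: ScaledCoefficientMatrix) -> float:
    """The anchoring factor ``a`` (= the respondent's utility range).

    Position-of-dead: ``a = 1/d`` where ``d`` is the scaled disutility of
    the equal-to-dead state (so that state gets value 0 after anchoring).
    Dead-VAS with worst-state rating ``v``: ``a = 1 - v/100`` (so the
    worst state gets value ``v/100``).
    """
    if anchor.kind == "position_of_dead":
        if anchor.state is None:
            raise ValueError("position-of-dead anchor needs a state")
        d = matrix.disutility(anchor.state)
        if d <= 0.0:
            raise ValueError(
                f"equal-to-dead state {anchor.state.code!r} has zero scaled "
                "disutility; dead cannot equal full health"
            )
        return 1.0 / d
    if anchor.vas is None:
        raise ValueError("dead-VAS anchor needs a value")
    a = 1.0 - anchor.vas / 100.0
    if a == 0.0:
        warnings.warn(
            "Dead-VAS of 100 gives anchoring factor 0: every state is valued 1",
            stacklevel=2,
        )
    return a


@dataclass(frozen=True)
class PersonalValueSet:
    """An anchored personal value set: ``V(h) = 1 - sum of anchored cells``.

    ``matrix`` holds the anchored coefficients ``M = a * M~``.  The
    anchoring factor ``a`` is kept explicitly so the respondent's utility
    range stays reportable; ``anchor`` records which variant produced it.
    """

    matrix: np.ndarray
    anchoring_factor: float
    anchor: Anchor
    system: DescriptiveSystem

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))

    @property
    def scaled_matrix(self) -> np.ndarray:
        """The pre-anchoring 1-0 scaled matrix (undefined when ``a == 0``)."""
        return self.matrix / self.anchoring_factor

    @property
    def worst_state_value(self) -> float:
        return self.value(self.system.worst_state())

    def value(self, state: HealthState | str) -> float:
        state = _as_state(state, self.system)
        idx = np.asarray(state.levels) - 1
        return 1.0 - float(self.matrix[idx, np.arange(self.system.n_dimensions)].sum())

    def values(self, states: Sequence[HealthState]) -> np.ndarray:
        idx = np.array([s.levels for s in states]) - 1
        return 1.0 - self.matrix[idx, np.arange(self.system.n_dimensions)].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format coefficient table (one row per level-dimension cell)."""
        rows = []
        for j, dim in enumerate(self.system.dimensions):
            for lvl in range(1, self.matrix.shape[0] + 1):
                rows.append(
                    {
                        "dimension": dim.code,
                        "level": lvl,
                        "coefficient": self.matrix[lvl - 1, j],
                    }
                )
        out = pd.DataFrame(rows)
        out.attrs["anchoring_factor"] = self.anchoring_factor
        out.attrs["anchor_kind"] = self.anchor.kind
        return out

    def value_table(self) -> pd.DataFrame:
        """Values for every state of the system (one row per state code)."""
        states = enumerate_states(self.system)
        return pd.DataFrame(
            {"state": [s.code for s in states], "value": self.values(states)}
        )


def anchor_matrix(
    matrix: ScaledCoefficientMatrix, a: float, anchor: Anchor | None = None
) -> PersonalValueSet:
    """Rescale the 1-0 matrix by the anchoring factor onto the QALY scale."""
    if a < 0.0:
        raise ValueError(f"anchoring factor must be non-negative, got {a}")
    if anchor is None:
        anchor = Anchor.dead_vas(100.0 * (1.0 - a)) if a <= 1.0 else Anchor(
            kind="position_of_dead"
        )
    return PersonalValueSet(
        matrix=a * matrix.values,
        anchoring_factor=a,
        anchor=anchor,
        system=matrix.system,
    )


# ---------------------------------------------------------------------------
# ranking

def rank_all_states(
    matrix: ScaledCoefficientMatrix, seed: int | np.random.Generator = 0
) -> list[HealthState]:
    """All states ordered best to worst by scaled value; ties broken randomly.

    Returns the full preference order (index 0 = rank 1 = best).  States
    with exactly equal scaled values — which arise whenever a weight is
    zero or ratings coincide — are permuted uniformly at random, and the
    result is deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = enumerate_states(matrix.system)
    disut = matrix.disutilities(states)
    tie_break = rng.permutation(len(states))
    order = np.lexsort((tie_break, disut))  # ascending disutility = descending value
    return [states[i] for i in order]


def _as_state(state: HealthState | str, system: DescriptiveSystem) -> HealthState:
    if isinstance(state, HealthState):
        return state
    return parse_state(state, system)
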