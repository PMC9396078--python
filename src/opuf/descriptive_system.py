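"""Generic dimensions-by-levels health descriptive systems.

A descriptive system defines health states as combinations of severity
levels on a fixed set of dimensions.  The EQ-5D-5L — five dimensions
(mobility, self-care, usual activities, pain/discomfort,
anxiety/depression) with five severity levels each, hence 3,125 states —
is bundled as the default, but any system with >=1 dimensions and >=2
levels per dimension is supported.

Level index 1 is always the best level ("no problems") and ``n_levels``
the worst, matching the digit-code convention in which ``"11111"`` is
full health and ``"55555"`` the worst state of the EQ-5D-5L.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Dimension",
    "DescriptiveSystem",
    "HealthState",
    "StateValidationError",
    "eq5d5l",
    "parse_state",
    "state_code",
    "enumerate_states",
    "dominates",
]


class StateValidationError(ValueError):
    """A health-state code or level vector violates the descriptive system."""


@dataclass(frozen=True)
class Dimension:
    """One dimension (criterion) of a descriptive system.

    Parameters
    ----------
    code : str
        Short identifier, e.g. ``"MO"`` for mobility.
    name : str
        Display name.
    levels : tuple of str
        Level labels ordered best to worst; at least two.
    """

    code: str
    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(
                f"dimension {self.code!r} needs at least 2 levels, got {len(self.levels)}"
            )
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DescriptiveSystem:
    """An ordered collection of :class:`Dimension` objects."""

    dimensions: tuple[Dimension, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("a descriptive system needs at least one dimension")
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        codes = [d.code for d in self.dimensions]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate dimension codes: {codes}")

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_levels(self) -> tuple[int, ...]:
        """Number of levels per dimension, in dimension order."""
        return tuple(d.n_levels for d in self.dimensions)

    @property
    def n_states(self) -> int:
        """Total number of states (product of level counts)."""
        n = 1
        for k in self.n_levels:
            n *= k
        return n

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.dimensions)

    @property
    def uses_delimited_codes(self) -> bool:
        """Delimited codes like ``"1-12-3"`` are used when any dimension has >9 levels."""
        return any(k > 9 for k in self.n_levels)

    def worst_state(self) -> "HealthState":
        return HealthState.from_levels(self.n_levels, self)

    def best_state(self) -> "HealthState":
        return HealthState.from_levels((1,) * self.n_dimensions, self)

    @classmethod
    def from_dict(cls, spec: dict) -> "DescriptiveSystem":
        dims = tuple(
            Dimension(code=d["code"], name=d.get("name", d["code"]), levels=tuple(d["levels"]))
            for d in spec["dimensions"]
        )
        return cls(dimensions=dims, name=spec.get("name", "custom"))

    @classmethod
    def from_yaml(cls, path) -> "DescriptiveSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class HealthState:
    """One health state: a vector of level indices (1 = best) plus its code."""

    levels: tuple[int, ...]
    code: str

    @classmethod
    def from_levels(cls, levels: Sequence[int], system: DescriptiveSystem) -> "HealthState":
        levels = tuple(int(v) for v in levels)
        if len(levels) != system.n_dimensions:
            raise StateValidationError(
                f"expected {system.n_dimensions} levels, got {len(levels)}"
            )
        for pos, (lvl, n) in enumerate(zip(levels, system.n_levels)):
            if not 1 <= lvl <= n:
                raise StateValidationError(
                    f"level {lvl} out of range [1, {n}] at position {pos + 1} "
                    f"({system.dimensions[pos].code})"
                )
        return cls(levels=levels, code=state_code(levels, system))


def state_code(levels: Sequence[int], system: DescriptiveSystem) -> str:
    """Render a level vector as a code string (``"12345"`` or ``"1-12-3"``)."""
    sep = "-" if system.uses_delimited_codes else ""
    return sep.join(str(v) for v in levels)


def parse_state(code: str, system: DescriptiveSystem) -> HealthState:
    """Parse a state code into a :class:`HealthState`.

    For plain digit codes the code length must equal the number of
    dimensions and every character must be a digit within the level range
    of its dimension (in dimension order).  Systems with >9 levels on any
    dimension use ``-``-delimited codes instead.

    Raises
    ------
    StateValidationError
        If the code has the wrong length, contains non-digits, or any
        level is out of range; the message names the offending position.
    """
    if system.uses_delimited_codes:
        parts = str(code).split("-")
    else:
        parts = list(str(code))
    if len(parts) != system.n_dimensions:
        raise StateValidationError(
            f"code {code!r} has {len(parts)} positions, expected {system.n_dimensions}"
        )
    levels = []
    for pos, part in enumerate(parts):
        if not part.isdigit():
            raise StateValidationError(
                f"code {code!r}: non-digit {part!r} at position {pos + 1}"
            )
        levels.append(int(part))
    return HealthState.from_levels(levels, system)


def enumerate_states(system: DescriptiveSystem) -> list[HealthState]:
    """All states of the system, lexicographically ordered by level vector.

    The size of the result equals the product of the per-dimension level
    counts — 3,125 for the EQ-5D-5L.
    """
    ranges = [range(1, n + 1) for n in system.n_levels]
    return [
        HealthState(levels=combo, code=state_code(combo, system))
        for combo in itertools.product(*ranges)
    ]


def dominates(a: HealthState, b: HealthState) -> bool:
    """True iff ``a`` dominates ``b``.

    ``a`` dominates ``b`` when it is at least as good (level index <=) on
    every dimension and strictly better on at least one.  This is a strict
    partial order; incomparable pairs return ``False`` in both directions.
    """
    if len(a.levels) != len(b.levels):
        raise StateValidationError(
            f"dimension count mismatch: {len(a.levels)} vs {len(b.levels)}"
        )
    at_least_as_good = all(x <= y for x, y in zip(a.levels, b.levels))
    strictly_better = any(x < y for x, y in zip(a.levels, b.levels))
    return at_least_as_good and strictly_better


def eq5d5l() -> DescriptiveSystem:
    """The bundled EQ-5D-5L descriptive system (5 dimensions x 5 levels)."""
    with resources.files("opuf.data").joinpath("eq5d5l.yaml").open() as fh:
        return DescriptiveSystem.from_dict(yaml.safe_load(fh))
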