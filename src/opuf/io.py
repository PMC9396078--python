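"""Respondent records, file formats and run configuration.

CSV is the canonical tabular interchange: one respondent per row, with
nested task responses (ratings, ranking, weights, DCE observations,
position-of-dead answers, demographics) JSON-encoded in their cells.
JSON files carry the same records as a list of objects.  Value sets
round-trip through long-format CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .descriptive_system import DescriptiveSystem, eq5d5l, parse_state
from .puf_core import Anchor, PersonalValueSet

__all__ = [
    "DceObservation",
    "RespondentRecord",
    "RunConfig",
    "SchemaError",
    "read_respondents",
    "write_respondents",
    "read_valueset",
    "write_valueset",
]

_JSON_COLUMNS = ("ratings", "ranking", "weights", "dce", "pod_answers", "demographics", "durations")


class SchemaError(ValueError):
    """One or more rows of a respondent file violate the schema."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {r}: {msg}" for r, msg in row_errors)
        super().__init__(f"{len(row_errors)} invalid record(s): {lines}")


@dataclass(frozen=True)
class DceObservation:
    """One answered validation-DCE comparison."""

    state_a: str
    state_b: str
    choice: Literal["A", "B"]
    target_distance: float | None = None
    percentile: int | None = None

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ValueError(f"choice must be 'A' or 'B', got {self.choice!r}")


@dataclass(frozen=True)
class RespondentRecord:
    """Raw survey responses for one respondent.

    ``ratings`` follow level order best to worst; ``weights`` follow the
    descriptive system's dimension order; ``ranking`` lists dimension
    codes from most to least important (a strict permutation — ties are
    not permitted).  ``dead_vas`` must be present exactly when the first
    position-of-dead answer preferred the shown (worst) state over dead.
    """

    respondent_id: str
    ratings: tuple[float, ...]
    ranking: tuple[str, ...]
    weights: tuple[float, ...]
    pod_answers: tuple[str, ...] = ()
    dead_vas: float | None = None
    dce: tuple[DceObservation, ...] = ()
    own_state: str | None = None
    eq_vas: float | None = None
    demographics: dict = field(default_factory=dict)
    durations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratings", tuple(float(v) for v in self.ratings))
        object.__setattr__(self, "ranking", tuple(str(c) for c in self.ranking))
        object.__setattr__(self, "weights", tuple(float(v) for v in self.weights))
        object.__setattr__(self, "pod_answers", tuple(self.pod_answers))
        object.__setattr__(
            self,
            "dce",
            tuple(d if isinstance(d, DceObservation) else DceObservation(**d) for d in self.dce),
        )
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError(
                f"dimension ranking must be a permutation without ties: {self.ranking}"
            )
        for ans in self.pod_answers:
            if ans not in ("state", "dead"):
                raise ValueError(f"position-of-dead answers must be 'state' or 'dead': {ans!r}")
        if self.pod_answers:
            routed_to_vas = self.pod_answers[0] == "state"
            if routed_to_vas and self.dead_vas is None:
                raise ValueError(
                    "worst state preferred over dead but no Dead-VAS value recorded"
                )
            if not routed_to_vas and self.dead_vas is not None:
                raise ValueError(
                    "Dead-VAS value recorded although the first position-of-dead "
                    "answer preferred dead"
                )

    def validate_against(self, system: DescriptiveSystem) -> None:
        """Cross-check field shapes and codes against a descriptive system."""
        if sorted(self.ranking) != sorted(system.codes):
            raise ValueError(
                f"ranking {self.ranking} is not a permutation of {system.codes}"
            )
        if len(self.weights) != system.n_dimensions:
            raise ValueError(
                f"{len(self.weights)} weights for {system.n_dimensions} dimensions"
            )
        if len(self.ratings) != system.n_levels[0]:
            raise ValueError(
                f"{len(self.ratings)} ratings for {system.n_levels[0]} levels"
            )
        if self.own_state is not None:
            parse_state(self.own_state, system)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dce"] = [asdict(o) for o in self.dce]
        for k in ("ratings", "ranking", "weights", "pod_answers"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RespondentRecord":
        d = dict(d)
        d["dce"] = tuple(DceObservation(**o) for o in d.get("dce", ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# respondent files

def write_respondents(
    records: Sequence[RespondentRecord], path, fmt: str | None = None
) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    dicts = [r.to_dict() for r in records]
    if fmt == "json":
        path.write_text(json.dumps(dicts, indent=1))
        return
    rows = []
    for d in dicts:
        row = dict(d)
        for col in _JSON_COLUMNS:
            row[col] = json.dumps(d[col])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_respondents(
    path, fmt: str | None = None, system: DescriptiveSystem | None = None
) -> list[RespondentRecord]:
    """Load and validate respondent records.

    Row-level problems are collected and reported together with their
    row numbers (1-based, excluding the header) in a :class:`SchemaError`.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "json":
        dicts = json.loads(path.read_text())
        if not isinstance(dicts, list):
            raise SchemaError([(1, "expected a JSON list of record objects")])
    else:
        df = pd.read_csv(path, dtype={"respondent_id": str, "own_state": str})
        if df.empty:
            raise SchemaError([(1, "file contains no records")])
        dicts = []
        for row in df.to_dict("records"):
            d = {k: (None if pd.isna(v) else v) for k, v in row.items() if not _is_json_col_nan(k, v)}
            for col in _JSON_COLUMNS:
                if col in d and isinstance(d[col], str):
                    d[col] = json.loads(d[col])
            dicts.append(d)
    if not dicts:
        raise SchemaError([(1, "file contains no records")])

    records, errors = [], []
    for i, d in enumerate(dicts, start=1):
        try:
            rec = RespondentRecord.from_dict(d)
            if system is not None:
                rec.validate_against(system)
            records.append(rec)
        except (TypeError, ValueError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise SchemaError(errors)
    return records


def _is_json_col_nan(k, v) -> bool:
    return k in _JSON_COLUMNS and not isinstance(v, str)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json",):
        return "json"
    return "csv"


# ---------------------------------------------------------------------------
# value-set files

def write_valueset(valueset: PersonalValueSet, path, respondent_id: str = "") -> None:
    """Long-format CSV: one row per coefficient, anchor metadata repeated."""
    frame = valueset.to_frame()
    frame.insert(0, "respondent_id", respondent_id)
    frame["anchoring_factor"] = valueset.anchoring_factor
    frame["anchor_kind"] = valueset.anchor.kind
    frame["anchor_ref"] = (
        valueset.anchor.state.code
        if valueset.anchor.kind == "position_of_dead" and valueset.anchor.state is not None
        else valueset.anchor.vas
    )
    frame.to_csv(path, index=False)


def read_valueset(path, system: DescriptiveSystem | None = None) -> PersonalValueSet:
    system = system or eq5d5l()
    df = pd.read_csv(path)
    n_levels = system.n_levels[0]
    matrix = np.zeros((n_levels, system.n_dimensions))
    for _, row in df.iterrows():
        j = system.codes.index(row["dimension"])
        matrix[int(row["level"]) - 1, j] = row["coefficient"]
    kind = df["anchor_kind"].iloc[0]
    if kind == "position_of_dead":
        anchor = Anchor.position_of_dead(parse_state(str(df["anchor_ref"].iloc[0]), system))
    else:
        anchor = Anchor.dead_vas(float(df["anchor_ref"].iloc[0]))
    return PersonalValueSet(
        matrix=matrix,
        anchoring_factor=float(df["anchoring_factor"].iloc[0]),
        anchor=anchor,
        system=system,
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Configuration for a full run (simulation, construction, aggregation)."""

    system_path: str | None = None
    statistic: str = "mean"
    n_bootstrap: int = 10_000
    seed: int = 0
    strict: bool = True
    population: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.system_path is not None and not Path(cfg.system_path).exists():
            raise FileNotFoundError(f"descriptive system file not found: {cfg.system_path}")
        return cfg

    def load_system(self) -> DescriptiveSystem:
        if self.system_path is None:
            return eq5d5l()
        return DescriptiveSystem.from_yaml(self.system_path)
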