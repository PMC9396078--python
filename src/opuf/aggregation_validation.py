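"""Group-level tariffs and consistency/validation statistics.

Personal value sets are aggregated cell-wise over their *anchored*
coefficient matrices (mean by default, median as the outlier-robust
alternative), with percentile-bootstrap confidence intervals obtained by
resampling whole respondents.  Validation statistics cover the
discrete-choice consistency of each respondent's value set, preference
reversals between the ranking and weighting tasks, and the spread of
utility ranges (the value of the worst state) across respondents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptive_tasks import ChoicePair, predict_choice
from .descriptive_system import DescriptiveSystem, HealthState, enumerate_states, parse_state
from .io import DceObservation, RespondentRecord
from .puf_core import PersonalValueSet

__all__ = [
    "GroupTariff",
    "ValidationReport",
    "aggregate",
    "bootstrap_ci",
    "group_tariff",
    "rescale_floor",
    "dce_accuracy",
    "reversal_count",
    "validation_report",
    "summary_table",
]

Statistic = Literal["mean", "median"]


@dataclass(frozen=True)
class GroupTariff:
    """Aggregated (group-level) coefficient matrix with bootstrap CIs."""

    matrix: np.ndarray
    statistic: str
    n: int
    system: DescriptiveSystem
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_bootstrap: int | None = None
    seed: int | None = None

    def value(self, state: HealthState | str) -> float:
        state = state if isinstance(state, HealthState) else parse_state(state, self.system)
        idx = np.asarray(state.levels) - 1
        return 1.0 - float(self.matrix[idx, np.arange(self.system.n_dimensions)].sum())

    def values(self, states: Sequence[HealthState]) -> np.ndarray:
        idx = np.array([s.levels for s in states]) - 1
        return 1.0 - self.matrix[idx, np.arange(self.system.n_dimensions)].sum(axis=1)

    def value_table(self) -> pd.DataFrame:
        states = enumerate_states(self.system)
        return pd.DataFrame(
            {"state": [s.code for s in states], "value": self.values(states)}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, dim in enumerate(self.system.dimensions):
            for lvl in range(1, self.matrix.shape[0] + 1):
                row = {
                    "dimension": dim.code,
                    "level": lvl,
                    "coefficient": self.matrix[lvl - 1, j],
                }
                if self.ci_lower is not None:
                    row["ci_lower"] = self.ci_lower[lvl - 1, j]
                    row["ci_upper"] = self.ci_upper[lvl - 1, j]
                rows.append(row)
        return pd.DataFrame(rows)


def _stacked(valuesets: Sequence[PersonalValueSet]) -> np.ndarray:
    if not valuesets:
        raise ValueError("need at least one personal value set")
    ref = valuesets[0].system
    for vs in valuesets:
        if vs.system.codes != ref.codes or vs.system.n_levels != ref.n_levels:
            raise ValueError("all value sets must share one descriptive system")
    return np.stack([vs.matrix for vs in valuesets])


def aggregate(
    valuesets: Sequence[PersonalValueSet], statistic: Statistic = "mean"
) -> GroupTariff:
    """Cell-wise mean or median of the anchored coefficient matrices."""
    arr = _stacked(valuesets)
    if statistic == "mean":
        matrix = arr.mean(axis=0)
    elif statistic == "median":
        matrix = np.median(arr, axis=0)
    else:
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    return GroupTariff(
        matrix=matrix, statistic=statistic, n=len(valuesets), system=valuesets[0].system
    )


def bootstrap_ci(
    valuesets: Sequence[PersonalValueSet],
    n_iter: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    statistic: Statistic = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell percentile-bootstrap CIs, resampling whole respondents."""
    arr = _stacked(valuesets)
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"bootstrap needs at least 2 respondents, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    reps = arr[idx]  # (n_iter, n, levels, dims)
    stats = reps.mean(axis=1) if statistic == "mean" else np.median(reps, axis=1)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(stats, alpha, axis=0)
    upper = np.quantile(stats, 1.0 - alpha, axis=0)
    return lower, upper


def group_tariff(
    valuesets: Sequence[PersonalValueSet],
    statistic: Statistic = "mean",
    n_bootstrap: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> GroupTariff:
    """Aggregate and attach bootstrap CIs in one call."""
    tariff = aggregate(valuesets, statistic)
    lower, upper = bootstrap_ci(valuesets, n_bootstrap, level, seed, statistic)
    return GroupTariff(
        matrix=tariff.matrix,
        statistic=statistic,
        n=tariff.n,
        system=tariff.system,
        ci_lower=lower,
        ci_upper=upper,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def summary_table(
    valuesets: Sequence[PersonalValueSet],
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Descriptive statistics of the personal coefficients, one row per cell
    (mean with bootstrap CI, min, quartiles, median, max)."""
    arr = _stacked(valuesets)
    lower, upper = bootstrap_ci(valuesets, n_bootstrap, seed=seed)
    system = valuesets[0].system
    rows = []
    for j, dim in enumerate(system.dimensions):
        for lvl in range(2, arr.shape[1] + 1):  # the level-1 row is all zeros
            cells = arr[:, lvl - 1, j]
            rows.append(
                {
                    "dimension": dim.code,
                    "level": lvl,
                    "mean": cells.mean(),
                    "ci_lower": lower[lvl - 1, j],
                    "ci_upper": upper[lvl - 1, j],
                    "min": cells.min(),
                    "q25": np.quantile(cells, 0.25),
                    "median": np.median(cells),
                    "q75": np.quantile(cells, 0.75),
                    "max": cells.max(),
                }
            )
    return pd.DataFrame(rows)


def rescale_floor(values, floor: float = -1.0) -> np.ndarray:
    """Linearly rescale negative values so the minimum equals ``floor``.

    Non-negative values are unchanged; negative values are multiplied by
    ``|floor| / |min|``.  If the minimum already lies at or above the
    floor the input is returned unchanged.  This is the common practice
    of bounding a social value set's worst-than-dead values at -1.
    """
    if floor >= 0:
        raise ValueError(f"floor must be negative, got {floor}")
    values = np.asarray(values, dtype=float)
    vmin = values.min()
    if vmin >= floor:
        return values.copy()
    out = values.copy()
    neg = out < 0
    out[neg] = out[neg] * (abs(floor) / abs(vmin))
    return out


# ---------------------------------------------------------------------------
# validation statistics

@dataclass(frozen=True)
class ValidationReport:
    """Consistency statistics for a set of respondents."""

    per_respondent_accuracy: tuple[float, ...]
    pooled_accuracy: float
    error_rate_by_distance: dict[float, float]
    n_choices: int
    reversal_counts: tuple[int, ...] = ()
    n_with_reversal: int = 0
    worst_value_summary: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "pooled_accuracy": self.pooled_accuracy,
            "n_choices": self.n_choices,
            "per_respondent_accuracy": list(self.per_respondent_accuracy),
            "error_rate_by_distance": {str(k): v for k, v in self.error_rate_by_distance.items()},
            "reversal_counts": list(self.reversal_counts),
            "n_with_reversal": self.n_with_reversal,
            "worst_value_summary": self.worst_value_summary,
        }
        return json.dumps(d, indent=1)

    def to_table(self) -> str:
        lines = [
            f"respondents:            {len(self.per_respondent_accuracy)}",
            f"DCE choices:            {self.n_choices}",
            f"pooled DCE accuracy:    {self.pooled_accuracy:.1%}",
        ]
        for dist in sorted(self.error_rate_by_distance):
            lines.append(
                f"  error rate @ {dist:.1f}:     {self.error_rate_by_distance[dist]:.1%}"
            )
        if self.reversal_counts:
            lines.append(f"with >=1 reversal:      {self.n_with_reversal}")
        if self.worst_value_summary:
            s = self.worst_value_summary
            lines.append(
                "worst-state value:      "
                f"min {s['min']:.2f} / median {s['median']:.2f} / "
                f"mean {s['mean']:.2f} / max {s['max']:.2f}"
            )
        return "\n".join(lines)


def dce_accuracy(
    valuesets: Sequence[PersonalValueSet],
    pairs: Sequence[Sequence[ChoicePair | DceObservation]],
    choices: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Fraction of observed choices matching the value-set predictions.

    ``pairs`` holds one sequence of comparisons per respondent.  When
    the comparisons are :class:`DceObservation` the observed choice is
    taken from each observation; otherwise ``choices`` must supply it.
    Accuracy is reported per respondent, pooled, and as error rates
    stratified by target utility distance.
    """
    if len(valuesets) != len(pairs):
        raise ValueError(f"{len(valuesets)} value sets but {len(pairs)} pair lists")
    if choices is not None and len(choices) != len(pairs):
        raise ValueError("choices and pairs must align per respondent")

    rng = np.random.default_rng(seed)
    per_resp, matches, total = [], 0, 0
    by_dist_match: dict[float, list[int]] = {}
    for i, (vs, plist) in enumerate(zip(valuesets, pairs)):
        obs_choices = choices[i] if choices is not None else [p.choice for p in plist]
        if len(obs_choices) != len(plist):
            raise ValueError(
                f"respondent {i}: {len(plist)} pairs but {len(obs_choices)} choices"
            )
        ok = 0
        for pair, observed in zip(plist, obs_choices):
            cp = _as_choice_pair(pair, vs.system)
            predicted = predict_choice(vs, cp, rng)
            hit = int(predicted == observed)
            ok += hit
            if cp.target_distance is not None:
                by_dist_match.setdefault(round(cp.target_distance, 6), []).append(hit)
        per_resp.append(ok / len(plist) if plist else float("nan"))
        matches += ok
        total += len(plist)

    if total == 0:
        raise ValueError("no choices to score")
    error_by_dist = {
        d: 1.0 - float(np.mean(hits)) for d, hits in sorted(by_dist_match.items())
    }
    return ValidationReport(
        per_respondent_accuracy=tuple(per_resp),
        pooled_accuracy=matches / total,
        error_rate_by_distance=error_by_dist,
        n_choices=total,
    )


def _as_choice_pair(pair, system) -> ChoicePair:
    if isinstance(pair, ChoicePair):
        return pair
    return ChoicePair(
        state_a=parse_state(pair.state_a, system),
        state_b=parse_state(pair.state_b, system),
        target_distance=pair.target_distance,
        achieved_distance=float("nan"),
        percentile=pair.percentile or 0,
    )


def reversal_count(
    ranking: Sequence[str], raw_weights: Mapping[str, float]
) -> int:
    """Number of dimension pairs whose swing weights contradict the ranking.

    A pair (i, j) counts when the ranking places i strictly above j but
    the raw weight of i is strictly below that of j; weight ties never
    count as violations.
    """
    count = 0
    for i in range(len(ranking)):
        for j in range(i + 1, len(ranking)):
            if raw_weights[ranking[i]] < raw_weights[ranking[j]]:
                count += 1
    return count


def validation_report(
    valuesets: Sequence[PersonalValueSet],
    records: Sequence[RespondentRecord],
    seed: int = 0,
) -> ValidationReport:
    """Full report: DCE consistency, ranking-vs-weight reversals, and the
    distribution of worst-state values across respondents."""
    if len(valuesets) != len(records):
        raise ValueError("value sets and records must align")
    base = dce_accuracy(valuesets, [r.dce for r in records], seed=seed)

    reversals = []
    for vs, rec in zip(valuesets, records):
        weights = dict(zip(vs.system.codes, rec.weights))
        reversals.append(reversal_count(rec.ranking, weights))

    worst = np.array([vs.worst_state_value for vs in valuesets])
    return ValidationReport(
        per_respondent_accuracy=base.per_respondent_accuracy,
        pooled_accuracy=base.pooled_accuracy,
        error_rate_by_distance=base.error_rate_by_distance,
        n_choices=base.n_choices,
        reversal_counts=tuple(reversals),
        n_with_reversal=int(sum(1 for r in reversals if r > 0)),
        worst_value_summary={
            "min": float(worst.min()),
            "median": float(np.median(worst)),
            "mean": float(worst.mean()),
            "max": float(worst.max()),
        },
    )
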