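"""Respondent-adaptive survey algorithms.

Two algorithms personalise the survey to each respondent's own 1-0
scaled value function:

* The **position-of-dead search** locates "being dead" within the
  respondent's ranked list of states using at most six paired
  comparisons: the worst state first, then an interval-halving search
  over rank positions (the median state, then five halving iterations in
  total).  With 3,125 states this pins the equal-to-dead state down to a
  maximum rank error of +/- 49.
* The **validation-DCE selector** builds three personalised paired
  comparisons from the 25th/50th/75th percentile states of the ranking,
  each matched with a partner at a target scaled-utility distance of
  about 0.1 (hard), 0.2 (medium) or 0.3 (easy); dominated/dominating
  pairs are excluded, and all ordering is randomised under an explicit
  seed.

Both are pure functions of (inputs, seed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .descriptive_system import HealthState, dominates
from .puf_core import PersonalValueSet, ScaledCoefficientMatrix

__all__ = [
    "PodSession",
    "PodResult",
    "ChoicePair",
    "PodProtocolError",
    "PREFERS_STATE",
    "PREFERS_DEAD",
    "pod_start",
    "pod_step",
    "pod_run",
    "select_validation_pairs",
    "predict_choice",
]

PREFERS_STATE = "state"
PREFERS_DEAD = "dead"
N_HALVING_ITERATIONS = 5

PodAnswer = Literal["state", "dead"]


class PodProtocolError(RuntimeError):
    """The position-of-dead session was used out of protocol order."""


def _label(state) -> str:
    # rankings usually hold HealthState objects, but the search itself only
    # needs rank positions, so any sortable token works
    return state.code if hasattr(state, "code") else str(state)


@dataclass(frozen=True)
class PodResult:
    """Outcome of a position-of-dead session.

    Either the respondent prefers the worst state over dead (route them
    to the Dead-VAS task), or an equal-to-dead state was located, with
    its rank and the guaranteed maximum rank error ceil(N / 2**6).
    """

    prefers_worst_over_dead: bool
    state: HealthState | None = None
    rank: int | None = None
    max_rank_error: int | None = None


@dataclass
class PodSession:
    """State of one position-of-dead interval-halving search.

    The ranking (index 0 = rank 1 = best) must come from the
    respondent's own scaled value function.  ``current_state`` is the
    state to present against "being dead"; feed each answer through
    :func:`pod_step`.
    """

    ranking: list[HealthState]
    current_state: HealthState | None = None
    current_rank: int | None = None  # 1-based
    lo: int | None = None
    hi: int | None = None
    iteration: int = 0  # halving iterations completed
    n_comparisons: int = 0  # comparisons answered
    history: list[dict] = field(default_factory=list)
    result: PodResult | None = None

    @property
    def n_states(self) -> int:
        return len(self.ranking)

    @property
    def is_terminal(self) -> bool:
        return self.result is not None

    def to_log(self) -> str:
        """JSON session log: every comparison, answer and bracket."""
        return json.dumps(
            {
                "n_states": self.n_states,
                "history": self.history,
                "result": None
                if self.result is None
                else {
                    "prefers_worst_over_dead": self.result.prefers_worst_over_dead,
                    "state": None if self.result.state is None else _label(self.result.state),
                    "rank": self.result.rank,
                    "max_rank_error": self.result.max_rank_error,
                },
            }
        )


def pod_start(ranking: Sequence[HealthState]) -> PodSession:
    """Open a session; the first comparison presents the worst-ranked state."""
    ranking = list(ranking)
    if not ranking:
        raise ValueError("ranking must be non-empty")
    session = PodSession(ranking=ranking)
    session.current_state = ranking[-1]
    session.current_rank = len(ranking)
    return session


def pod_step(session: PodSession, answer: PodAnswer) -> PodSession:
    """Record an answer to the currently presented comparison.

    ``answer`` is ``"state"`` (the shown state is preferred over being
    dead) or ``"dead"``.  The first ``"state"`` answer terminates with
    the Dead-VAS route.  A first ``"dead"`` answer starts the halving
    search over rank positions: the next probe is the median state, and
    each subsequent answer halves the bracket — ``"dead"`` moves it
    toward better-ranked states, ``"state"`` toward worse-ranked ones.
    After five halving probes the midpoint of the remaining bracket is
    returned as the equal-to-dead state.
    """
    if session.is_terminal:
        raise PodProtocolError("session already terminated")
    if session.current_state is None:
        raise PodProtocolError("no comparison is pending")
    if answer not in (PREFERS_STATE, PREFERS_DEAD):
        raise ValueError(f"answer must be {PREFERS_STATE!r} or {PREFERS_DEAD!r}")

    n = session.n_states
    session.n_comparisons += 1
    first = session.lo is None
    session.history.append(
        {
            "comparison": session.n_comparisons,
            "state": _label(session.current_state),
            "rank": session.current_rank,
            "answer": answer,
            "bracket": None if first else [session.lo, session.hi],
        }
    )

    if first:
        if answer == PREFERS_STATE:
            # worst state preferred over dead: no state is worse than dead
            session.result = PodResult(prefers_worst_over_dead=True)
            session.current_state = None
            session.current_rank = None
            return session
        session.lo, session.hi = 1, n
    else:
        # the probed rank bounds the threshold (best-ranked dead-or-worse state)
        if answer == PREFERS_DEAD:
            session.hi = session.current_rank
        else:
            session.lo = session.current_rank + 1
        session.iteration += 1

    if session.iteration >= N_HALVING_ITERATIONS or session.lo > session.hi:
        final = max(1, min(n, (session.lo + session.hi) // 2))
        session.result = PodResult(
            prefers_worst_over_dead=False,
            state=session.ranking[final - 1],
            rank=final,
            max_rank_error=math.ceil(n / 2 ** (N_HALVING_ITERATIONS + 1)),
        )
        session.current_state = None
        session.current_rank = None
        return session

    probe = (session.lo + session.hi) // 2
    session.current_rank = probe
    session.current_state = session.ranking[probe - 1]
    return session


def pod_run(ranking: Sequence[HealthState], answers: Sequence[PodAnswer]) -> PodResult:
    """Replay a recorded answer sequence through a fresh session."""
    session = pod_start(ranking)
    for ans in answers:
        pod_step(session, ans)
    if not session.is_terminal:
        raise PodProtocolError(
            f"answer sequence of length {len(answers)} did not terminate the search"
        )
    return session.result


# ---------------------------------------------------------------------------
# validation-DCE choice-set selection

@dataclass(frozen=True)
class ChoicePair:
    """One personalised paired comparison for the validation DCE."""

    state_a: HealthState
    state_b: HealthState
    target_distance: float
    achieved_distance: float
    percentile: int


def select_validation_pairs(
    matrix: ScaledCoefficientMatrix,
    ranking: Sequence[HealthState],
    seed: int | np.random.Generator = 0,
    targets: Sequence[float] = (0.1, 0.2, 0.3),
    percentiles: Sequence[int] = (25, 50, 75),
) -> list[ChoicePair]:
    """Pick the three personalised validation choice sets.

    Scenario-A states sit at the 25th/50th/75th percentile ranks
    (nearest-rank, counting rank 1 = best) of the respondent's ranking.
    Each is paired with the state whose absolute scaled-value distance is
    closest to its target (0.1/0.2/0.3, assignment randomised).  States
    that dominate or are dominated by the A-state are ineligible, as are
    the A-states themselves; ties are broken by the seed, and the three
    pairs are returned in randomised presentation order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranking = list(ranking)
    n = len(ranking)
    if n < 2:
        raise ValueError("ranking too small to form pairs")

    values = 1.0 - matrix.disutilities(ranking)
    levels = np.array([s.levels for s in ranking])

    a_indices = []
    for q in percentiles:
        rank = int(round(q / 100.0 * n))
        a_indices.append(min(max(rank, 1), n) - 1)
    target_order = [targets[i] for i in rng.permutation(len(targets))]

    pairs = []
    for pos, (a_idx, target) in enumerate(zip(a_indices, target_order)):
        a_state = ranking[a_idx]
        a_lvl = levels[a_idx]
        # dominance in either direction makes the pair uninformative
        a_dominates = (a_lvl <= levels).all(axis=1) & (a_lvl < levels).any(axis=1)
        b_dominates = (levels <= a_lvl).all(axis=1) & (levels < a_lvl).any(axis=1)
        eligible = ~(a_dominates | b_dominates)
        eligible[a_indices] = False  # A-states must stay distinct from all members
        if not eligible.any():
            warnings.warn(
                f"no non-dominated partner for state {a_state.code}; "
                "substituting the nearest eligible state",
                stacklevel=2,
            )
            eligible = np.ones(n, dtype=bool)
            eligible[a_indices] = False
        gap = np.abs(np.abs(values - values[a_idx]) - target)
        gap[~eligible] = np.inf
        best = np.flatnonzero(gap == gap.min())
        b_idx = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
        pairs.append(
            ChoicePair(
                state_a=a_state,
                state_b=ranking[b_idx],
                target_distance=float(target),
                achieved_distance=float(abs(values[b_idx] - values[a_idx])),
                percentile=int(percentiles[pos]),
            )
        )

    return [pairs[i] for i in rng.permutation(len(pairs))]


def predict_choice(
    valueset: PersonalValueSet,
    pair: ChoicePair,
    seed: int | np.random.Generator = 0,
) -> str:
    """Predicted choice: the higher-valued scenario ('A' or 'B'); exact ties
    are broken by a seeded coin flip."""
    va = valueset.value(pair.state_a)
    vb = valueset.value(pair.state_b)
    if va > vb:
        return "A"
    if vb > va:
        return "B"
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "A" if rng.integers(2) == 0 else "B"
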