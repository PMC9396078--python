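"""Synthetic respondents with known latent preferences.

Each simulated respondent carries a latent preference structure — true
level disutilities, true normalised swing weights, a true value for the
worst state (equivalently an anchoring factor), and a choice-noise scale
``beta`` — and produces survey responses in the same format a real
respondent would: level ratings, a dimension ranking, raw swing weights,
position-of-dead answers (consistent with the latent value of each
probed state), a Dead-VAS value when the worst state beats dead, and
discrete choices drawn from a logistic random-utility rule

    P(choose A) = 1 / (1 + exp(-beta * (V_A - V_B)))

on the 1-0 scaled values.  Default population parameters emulate the
dispersion seen in small general-population valuation samples: mean
interior level ratings near 79/55/23, swing weights mostly high with
occasional zeros and all-100 responders, about 36% of respondents
preferring the worst state over dead, and worst-state values spanning
roughly +0.7 down to about -3.

The embedded latent truth makes end-to-end parameter-recovery checks
possible: with noiseless responses and a Dead-VAS anchor the
reconstructed value set equals the latent one exactly; with a
position-of-dead anchor it matches up to the search's +/- 49-rank
resolution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .adaptive_tasks import (
    PREFERS_DEAD,
    PREFERS_STATE,
    pod_start,
    pod_step,
    select_validation_pairs,
)
from .descriptive_system import DescriptiveSystem, eq5d5l
from .io import DceObservation, RespondentRecord
from .puf_core import (
    LevelDisutilities,
    ScaledCoefficientMatrix,
    SwingWeights,
    build_matrix,
    rank_all_states,
)

__all__ = [
    "PopulationConfig",
    "LatentPreference",
    "SimulatedRespondent",
    "sample_latent",
    "simulate_survey",
    "simulate_population",
    "ranking_seed_for",
]


def ranking_seed_for(respondent_id: str) -> int:
    """Deterministic per-respondent seed for value ties and choice-set draws.

    Derived from the respondent id so that reconstructing a value set
    from a stored record reproduces the exact ranking (and hence the
    equal-to-dead state) the adaptive tasks used during the survey.
    """
    return zlib.crc32(str(respondent_id).encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class PopulationConfig:
    """Distributional parameters of the synthetic respondent population.

    Interior level ratings are drawn from clipped normals (best to worst
    interior level); swing weights combine an all-100 point mass, a
    per-dimension zero point mass and a Beta bulk scaled to (0, 100);
    the worst-state value is positive (Dead-VAS route) with probability
    ``p_worst_over_dead``, uniform on ``worst_value_positive_range``,
    and otherwise ``-10**u`` with ``u`` uniform on
    ``worst_value_negative_log10_range``.
    """

    rating_means: tuple[float, ...] = (79.1, 54.9, 23.5)
    rating_sds: tuple[float, ...] = (11.5, 13.4, 11.3)
    rating_noise_sd: float = 0.0
    p_all_weights_100: float = 0.08
    p_zero_weight: float = 0.037
    weight_beta_shape: tuple[float, float] = (1.6, 0.62)
    p_worst_over_dead: float = 0.36
    worst_value_positive_range: tuple[float, float] = (0.05, 0.7)
    worst_value_negative_log10_range: tuple[float, float] = (-2.0, 0.5)
    choice_beta: float = 8.0
    pod_error_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_all_weights_100", "p_zero_weight", "p_worst_over_dead", "pod_error_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.choice_beta < 0:
            raise ValueError(f"choice_beta must be >= 0, got {self.choice_beta}")
        if len(self.rating_means) != len(self.rating_sds):
            raise ValueError("rating_means and rating_sds must have equal length")


@dataclass(frozen=True)
class LatentPreference:
    """Ground-truth preference structure of one synthetic respondent."""

    disutilities: tuple[float, ...]  # monotone, endpoints 0 and 1
    weights: tuple[float, ...]  # normalised, sum 1
    worst_value: float  # latent value of the worst state
    choice_beta: float
    seed: int

    @property
    def anchoring_factor(self) -> float:
        return 1.0 - self.worst_value

    @property
    def prefers_worst_over_dead(self) -> bool:
        return self.worst_value > 0.0

    def scaled_matrix(self, system: DescriptiveSystem) -> ScaledCoefficientMatrix:
        w = SwingWeights(raw=tuple(100.0 * v / max(self.weights) for v in self.weights),
                         normalized=self.weights)
        return build_matrix(LevelDisutilities(self.disutilities), w, system)

    def value(self, matrix: ScaledCoefficientMatrix, state) -> float:
        """Latent anchored value of a state."""
        return 1.0 - self.anchoring_factor * matrix.disutility(state)

    def anchored_matrix(self, system: DescriptiveSystem) -> np.ndarray:
        return self.anchoring_factor * self.scaled_matrix(system).values

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedRespondent:
    """A survey record plus the latent truth it was generated from."""

    record: RespondentRecord
    latent: LatentPreference


def sample_latent(
    config: PopulationConfig,
    seed: int | np.random.Generator,
    system: DescriptiveSystem | None = None,
) -> LatentPreference:
    """Draw one latent preference from the population distributions."""
    system = system or eq5d5l()
    rng, seed_val = _rng_and_seed(seed)
    n_dims = system.n_dimensions

    interior = rng.normal(config.rating_means, config.rating_sds)
    interior = np.clip(interior, 0.5, 99.5)
    interior = np.sort(interior)[::-1]  # enforce monotone best to worst
    disutilities = (0.0, *(1.0 - interior / 100.0), 1.0)

    if rng.random() < config.p_all_weights_100:
        raw = np.full(n_dims, 100.0)
    else:
        raw = np.empty(n_dims)
        yardstick = rng.integers(n_dims)
        a, b = config.weight_beta_shape
        for j in range(n_dims):
            if j == yardstick:
                raw[j] = 100.0
            elif rng.random() < config.p_zero_weight:
                raw[j] = 0.0
            else:
                raw[j] = 100.0 * rng.beta(a, b)
    weights = tuple(raw / raw.sum())

    if rng.random() < config.p_worst_over_dead:
        worst = rng.uniform(*config.worst_value_positive_range)
    else:
        worst = -(10.0 ** rng.uniform(*config.worst_value_negative_log10_range))

    return LatentPreference(
        disutilities=tuple(float(v) for v in disutilities),
        weights=tuple(float(v) for v in weights),
        worst_value=float(worst),
        choice_beta=config.choice_beta,
        seed=seed_val,
    )


def simulate_survey(
    latent: LatentPreference,
    system: DescriptiveSystem | None = None,
    seed: int | np.random.Generator = 0,
    config: PopulationConfig | None = None,
    respondent_id: str | None = None,
) -> SimulatedRespondent:
    """Generate the full survey record implied by a latent preference."""
    system = system or eq5d5l()
    config = config or PopulationConfig()
    rng, seed_val = _rng_and_seed(seed)
    respondent_id = respondent_id or f"S{seed_val}"

    # Step 3: level ratings (interior levels may carry reporting noise)
    ratings = 100.0 * (1.0 - np.asarray(latent.disutilities))
    if config.rating_noise_sd > 0:
        ratings[1:-1] = np.clip(
            ratings[1:-1] + rng.normal(0.0, config.rating_noise_sd, len(ratings) - 2),
            0.5,
            99.5,
        )
        ratings[1:-1] = np.sort(ratings[1:-1])[::-1]

    # Steps 4-5: ranking by true swing magnitude (random tie order), raw weights
    w = np.asarray(latent.weights)
    jitter = rng.permutation(len(w))
    order = np.lexsort((jitter, -w))
    ranking = tuple(system.codes[i] for i in order)
    raw = 100.0 * w / w.max()
    raw[np.argmax(raw)] = 100.0  # the yardstick is exact by task design
    raw_weights = tuple(float(v) for v in raw)

    matrix = latent.scaled_matrix(system)
    rk_seed = ranking_seed_for(respondent_id)
    state_ranking = rank_all_states(matrix, rk_seed)

    # Step 7 (+8): position-of-dead answers from the latent value function
    session = pod_start(state_ranking)
    while not session.is_terminal:
        answer = (
            PREFERS_STATE
            if latent.value(matrix, session.current_state) > 0.0
            else PREFERS_DEAD
        )
        if config.pod_error_prob > 0 and rng.random() < config.pod_error_prob:
            answer = PREFERS_DEAD if answer == PREFERS_STATE else PREFERS_STATE
        pod_step(session, answer)
    pod_answers = tuple(h["answer"] for h in session.history)
    dead_vas = None
    if session.result.prefers_worst_over_dead:
        dead_vas = float(np.clip(100.0 * latent.worst_value, 0.0, 100.0))

    # Step 6: validation DCE with logistic choice noise on scaled values
    pairs = select_validation_pairs(matrix, state_ranking, np.random.default_rng(rk_seed + 1))
    dce = []
    for pair in pairs:
        dv = matrix.disutility(pair.state_b) - matrix.disutility(pair.state_a)
        if np.isinf(latent.choice_beta):
            p_a = 0.5 if dv == 0 else (1.0 if dv > 0 else 0.0)
        else:
            p_a = 1.0 / (1.0 + np.exp(-latent.choice_beta * dv))
        choice = "A" if rng.random() < p_a else "B"
        dce.append(
            DceObservation(
                state_a=pair.state_a.code,
                state_b=pair.state_b.code,
                choice=choice,
                target_distance=pair.target_distance,
                percentile=pair.percentile,
            )
        )

    # Steps 1-2, 9: own health, EQ-VAS, demographics (carried, never interpreted)
    own_levels = [
        int(rng.choice(np.arange(1, n + 1), p=_mild_state_probs(n)))
        for n in system.n_levels
    ]
    own_state = "".join(str(v) for v in own_levels) if not system.uses_delimited_codes \
        else "-".join(str(v) for v in own_levels)
    eq_vas = float(np.clip(np.round(rng.normal(78.0, 14.0)), 0.0, 100.0))
    demographics = {
        "age_band": str(rng.choice(["18-29", "30-44", "45-59", "60+"])),
        "sex": str(rng.choice(["female", "male", "other"], p=[0.5, 0.48, 0.02])),
        "education": str(rng.choice(["secondary", "vocational", "degree"])),
    }
    durations = {
        task: float(np.round(rng.lognormal(mean, 0.4), 1))
        for task, mean in [
            ("level_rating", np.log(49)),
            ("dimension_ranking", np.log(41)),
            ("dimension_weighting", np.log(62)),
            ("validation_dce", np.log(57)),
            ("position_of_dead", np.log(44)),
        ]
    }

    record = RespondentRecord(
        respondent_id=respondent_id,
        ratings=tuple(float(v) for v in ratings),
        ranking=ranking,
        weights=raw_weights,
        pod_answers=pod_answers,
        dead_vas=dead_vas,
        dce=tuple(dce),
        own_state=own_state,
        eq_vas=eq_vas,
        demographics=demographics,
        durations=durations,
    )
    return SimulatedRespondent(record=record, latent=latent)


def simulate_population(
    n: int,
    config: PopulationConfig | None = None,
    seed: int = 0,
    system: DescriptiveSystem | None = None,
) -> list[SimulatedRespondent]:
    """Draw ``n`` latents and simulate each one's survey, reproducibly."""
    config = config or PopulationConfig()
    system = system or eq5d5l()
    root = np.random.default_rng(seed)
    out = []
    for i in range(n):
        latent_seed = int(root.integers(2**31))
        survey_seed = int(root.integers(2**31))
        latent = sample_latent(config, latent_seed, system)
        out.append(
            simulate_survey(
                latent,
                system,
                survey_seed,
                config,
                respondent_id=f"S{i + 1:03d}",
            )
        )
    return out


def _mild_state_probs(n_levels: int) -> np.ndarray:
    # most people report no or slight problems on most dimensions
    p = 0.5 ** np.arange(n_levels)
    return p / p.sum()


def _rng_and_seed(seed) -> tuple[np.random.Generator, int]:
    if isinstance(seed, np.random.Generator):
        return seed, int(seed.integers(2**31))
    return np.random.default_rng(seed), int(seed)
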