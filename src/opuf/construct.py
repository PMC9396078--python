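"""Build a personal value set from one respondent's raw survey record.

This ties the pieces together: level ratings -> disutilities, raw swing
weights -> normalised weights, outer product -> scaled coefficient
matrix, and then anchoring — by replaying the respondent's recorded
position-of-dead answers against their own state ranking, or directly
from their Dead-VAS value.
"""

from __future__ import annotations

from .adaptive_tasks import pod_run
from .descriptive_system import DescriptiveSystem, eq5d5l
from .io import RespondentRecord
from .puf_core import (
    Anchor,
    PersonalValueSet,
    anchor_matrix,
    anchoring_factor,
    build_matrix,
    normalize_weights,
    ratings_to_disutilities,
)
from .puf_core import rank_all_states
from .respondent_sim import ranking_seed_for

__all__ = ["construct_valueset"]


def construct_valueset(
    record: RespondentRecord,
    system: DescriptiveSystem | None = None,
    *,
    strict: bool = True,
    ranking_seed: int | None = None,
) -> PersonalValueSet:
    """Construct the respondent's anchored personal value set.

    When the anchor comes from the position-of-dead task, the recorded
    answer sequence is replayed against the respondent's own ranking of
    all states.  Value ties in that ranking are broken randomly, so the
    tie-break seed must match the one used when the survey ran;
    by default it is derived deterministically from the respondent id
    (the convention the simulator uses).

    ``strict`` controls response validation: strict mode rejects
    non-monotone level ratings and a missing yardstick weight, lenient
    mode repairs/accepts them with a warning.
    """
    system = system or eq5d5l()
    record.validate_against(system)

    disutilities = ratings_to_disutilities(record.ratings, strict=strict)
    weights = normalize_weights(record.weights, strict=strict)
    matrix = build_matrix(disutilities, weights, system)

    if record.dead_vas is not None:
        anchor = Anchor.dead_vas(record.dead_vas)
    else:
        if not record.pod_answers:
            raise ValueError(
                f"respondent {record.respondent_id}: no anchor available "
                "(neither position-of-dead answers nor a Dead-VAS value)"
            )
        if ranking_seed is None:
            ranking_seed = ranking_seed_for(record.respondent_id)
        ranking = rank_all_states(matrix, ranking_seed)
        result = pod_run(ranking, record.pod_answers)
        if result.prefers_worst_over_dead:
            raise ValueError(
                f"respondent {record.respondent_id}: preferred the worst state "
                "over dead but recorded no Dead-VAS value"
            )
        anchor = Anchor.position_of_dead(result.state)

    a = anchoring_factor(anchor, matrix)
    return anchor_matrix(matrix, a, anchor)
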