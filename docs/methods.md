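# Methods

## Model and assumptions

The package implements an additive multi-attribute value function over a
dimensions-by-levels health descriptive system (EQ-5D-5L by default):

    V(h) = 1 − a · Σ_i l(h_i) · w_i

with level disutilities `l` (0 at "no problems", 1 at "extreme problems"),
normalised swing weights `w` (Σw = 1), and anchoring factor `a`. The model
assumes:

* **Additivity / preferential independence** — no interactions between
  dimensions; the value of a level on one dimension does not depend on the
  levels of the others.
* **A shared level function** — one set of severity-level ratings applies
  to every dimension, i.e. "moderate problems" means the same fraction of
  the dimension's swing everywhere. This is the elicitation design choice
  that keeps the task count low; it is an approximation, and the per-cell
  coefficients of the outer product inherit any misfit.
* **Utility independence from duration** — required for the QALY
  interpretation of the anchored scale.

All arithmetic is done at full floating-point precision. Rounding (half
away from zero, two decimals) exists only for display and export. When a
coefficient matrix is reconstructed from display-rounded cells, the
`ScaledCoefficientMatrix` validator accepts it with a loosened tolerance
(`atol=0.02`), since rounded rows need not sum exactly to 1.

## Elicitation components and their parameters

| Component | Scale | Constraint | Notes |
|---|---|---|---|
| Level ratings | 0–100 (% health remaining) | endpoints fixed at 100/0; non-increasing | strict mode rejects non-monotone ratings, lenient mode warns and accepts (the elicitation slider cannot enforce monotonicity) |
| Swing weights | 0–100 per dimension | max weight exactly 100 (yardstick) | zeros allowed; several dimensions may tie at 100; lenient mode rescales by the maximum when the yardstick is missing |
| Position-of-dead | choice sequence | ≤ 6 comparisons | see below |
| Dead-VAS | 0–100 | worst state between dead (0) and full health (100) | used only when the worst state is preferred over dead; `a = 1 − v/100`; `v = 100` degenerates to `a = 0` (every state valued 1) and triggers a warning |

The anchoring factor is stored explicitly on every `PersonalValueSet`
rather than folded silently into the coefficients, so each respondent's
utility range (equivalently the value of the worst state, `1 − a`) stays
reportable.

## Position-of-dead search

The respondent's scaled matrix values and ranks all states (ties broken
uniformly at random under an explicit seed; the ranking is treated as a
strict order thereafter). The first comparison presents the worst-ranked
state against "being dead". Preferring the state routes the respondent to
the Dead-VAS task after a single comparison. Preferring dead starts an
interval-halving search over rank positions 1..N: five probes, each at the
integer midpoint `(lo+hi)//2` of the current bracket; answering "dead"
moves the upper edge to the probe (the threshold lies at or above it),
answering "state" moves the lower edge past it. After the fifth probe the
**midpoint of the remaining bracket** is returned as the equal-to-dead
state.

Returning the final bracket's midpoint, rather than the last probed state,
is what achieves the ±49-state guarantee for N = 3,125: five halvings leave
a bracket of ≈ N/32 ≈ 98 ranks with the last probe sitting at its *edge*
(worst-case error 98), while the midpoint is at most ceil(N/2⁶) = 49 ranks
from any point of the bracket. The package verifies the bound exhaustively
over every consistent threshold t ∈ 1..3,125 (and the generalised bound
ceil(N/64) for smaller N). On rankings small enough for the bracket to
collapse before five probes, the search terminates early; with 3,125 states
it always uses exactly six comparisons (or one, on the Dead-VAS route).

## Validation-DCE choice sets

Scenario-A states are taken at the 25th/50th/75th percentile ranks of the
personal ranking, using the nearest-rank convention `round(q·N)` counted
from the best state. Each A-state is paired with the state minimising
`||V(A) − V(B)| − target|` for targets 0.1/0.2/0.3 (assignment order
randomised), excluding states that dominate or are dominated by the
A-state and the A-states themselves; ties among equally good partners are
broken by the seed, and the three pairs are presented in randomised order.
An argmin rule (rather than a fixed tolerance window) guarantees selection
always succeeds; on the 3,125-state grid the achieved distances are within
0.01 of the targets for typical matrices. Choice prediction returns the
higher-valued scenario, with exact ties decided by a seeded coin flip.

## Synthetic respondents

The simulator draws latent preferences and then generates the survey
responses those preferences imply, so every downstream computation can be
checked against ground truth. Default population parameters are chosen to
emulate the dispersion reported by small general-population valuation
pilots, not fitted to any dataset:

* interior level ratings ~ Normal(79.1, 11.5), Normal(54.9, 13.4),
  Normal(23.5, 11.3), clipped to (0.5, 99.5) and sorted to enforce
  monotonicity;
* swing weights: with probability 0.08 the respondent sets all five
  weights to 100; otherwise one uniformly chosen yardstick gets 100 and
  each other dimension is 0 with probability 0.037 or 100·Beta(1.6, 0.62)
  (mean ≈ 72, SD ≈ 25) otherwise;
* the worst state is preferred over dead with probability 0.36, in which
  case its latent value is Uniform(0.05, 0.7); otherwise it is
  −10^Uniform(−2, 0.5), spanning −0.01 to about −3.2 with median ≈ −0.18;
* discrete choices follow a logistic rule P(A) = 1/(1+exp(−β·ΔV)) on the
  1–0 scaled value difference with β = 8 by default (β = 0 is pure noise,
  β → ∞ noiseless); position-of-dead answers are deterministic in the
  latent value of the probed state, with an optional per-comparison flip
  probability for robustness studies.

Responses are emitted at full precision (no slider discretisation), which
is what makes exact parameter recovery checkable: Dead-VAS-routed
respondents reconstruct their latent values to < 1e-9; position-of-dead
respondents reconstruct an affine copy whose anchoring factor differs by
at most the latent value gap across ±49 ranks around the true threshold.
What the simulator deliberately does **not** emulate: integer slider
responses, attention lapses, scale-use heterogeneity on the rating task,
ranking/weighting inconsistencies (the simulated ranking is always
consistent with the weights, so simulated reversal counts are zero), or
correlations between demographics and preferences. Passing recovery tests
therefore demonstrates the correctness of the pipeline's arithmetic and
algorithms, not robustness to real response behaviour.

A per-respondent tie-break seed is derived from the respondent id
(CRC-32), so reconstructing a value set from a stored record reproduces
the exact ranking — and hence the same equal-to-dead state — that the
adaptive tasks used when the record was generated.

## Aggregation

Group tariffs are cell-wise means (or medians, the outlier-robust
alternative) of the **anchored** coefficient matrices — aggregation
operates on what each respondent's value set actually implies for state
values, not on the raw components. Confidence intervals are percentile
bootstrap (2.5/97.5) with 10,000 iterations by default, resampling whole
respondents rather than cells, deterministic under a seed. `rescale_floor`
applies the common social-value-set convention of linearly mapping the
negative value range so its minimum is −1, leaving zero and positive
values untouched; because this map is piecewise linear in values, it is
exposed as an operation on state values rather than on coefficients.

## Problem sizes used in tests

The bundled suite exercises the full 3,125-state system throughout: the
position-of-dead bound exhaustively over all thresholds, parameter
recovery and bootstrap behaviour on 50 synthetic respondents (10,000
bootstrap iterations), group-mean recovery on 200 respondents, and choice
-noise behaviour on samples of 80–150. These sizes keep the whole suite
around half a minute on one CPU while leaving no algorithmic path
unexercised at full scale.

## Known limitations

* Only main-effects (additive) value functions; no interaction terms or
  multiplicative aggregation.
* One shared level function across dimensions by design; systems whose
  dimensions have different level counts are representable but cannot be
  scored by this model.
* The percentile and nearest-rank conventions, the bracket orientation of
  the search, and the argmin pairing rule are reasonable fixed choices
  among several defensible ones; alternative conventions would shift
  selected choice sets and equal-to-dead states within the documented
  error bounds.
* Published sample-level summary tables from survey pilots depend on raw
  respondent data that is not redistributable; the package reproduces
  procedures and worked values, not sample statistics.
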