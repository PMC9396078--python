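# opuf

Personal and group-level health-state value sets from compositional
preference elicitation.

Conventional EQ-5D valuation studies ask hundreds of respondents to value
whole health states (by time trade-off or discrete choice) and then fit a
statistical model to decompose those valuations into dimension-level
coefficients. That works for populations but cannot produce a value set for
a *single person*. The compositional (OPUF-style) approach goes the other
way: each respondent values the **components** of health states directly —
severity-level ratings, swing weights for the five dimensions, and an
anchor locating "being dead" — and a complete personal utility function
(PUF) over all 3,125 EQ-5D-5L states is assembled arithmetically from those
few responses. Group tariffs are then simple cell-wise averages of personal
value sets.

This package is for health economists and valuation methodologists who want
to construct, simulate, validate and aggregate such value sets
programmatically.

## The model

For a health state *h* with level *h_i* on dimension *i*, the personal
value function is additive:

```
V(h) = 1 − a · Σ_i  l(h_i) · w_i
```

* `l(h_i)` — disutility of the severity level, `l = 1 − rating/100`, from a
  single set of 0–100 level ratings shared across dimensions (no problems =
  0, extreme problems = 1);
* `w_i` — normalised swing weight of dimension *i* (raw 0–100 weights with
  the most important dimension fixed at 100 as yardstick, normalised to sum
  to 1);
* `a` — the anchoring factor (the respondent's utility range), which maps
  the 1–0 scaled function onto the QALY scale where dead = 0. It comes
  either from the **position-of-dead** task (an adaptive six-comparison
  interval-halving search over the respondent's own ranking of all states,
  locating the state equal to being dead within ±49 ranks; `a = 1/d` for
  that state's scaled disutility `d`) or, for respondents who prefer the
  worst state over dead, from a **Dead-VAS** rating `v` of the worst state
  (`a = 1 − v/100`).

The outer product of the disutility and weight vectors gives a 5×5
coefficient matrix; multiplying it by `a` gives the anchored personal value
set. The package also implements the survey's personalised validation-DCE
choice-set selector, a synthetic-respondent simulator with known latent
preferences, and group aggregation (mean or median) with
respondent-resampling percentile-bootstrap confidence intervals.

## Worked example

A respondent rates the severity levels 100/90/50/30/0, assigns swing
weights 100 (mobility), 60 (self-care), 40 (usual activities), 80
(pain/discomfort), 70 (anxiety/depression), and the position-of-dead search
identifies state `51255` as equal to being dead:

```python
import opuf

system = opuf.eq5d5l()
l = opuf.ratings_to_disutilities([100, 90, 50, 30, 0])
w = opuf.normalize_weights([100, 60, 40, 80, 70])
matrix = opuf.build_matrix(l, w, system)
print("scaled value of 12345:", round(opuf.scaled_value(matrix, "12345"), 4))

anchor = opuf.Anchor.position_of_dead(opuf.parse_state("51255", system))
a = opuf.anchoring_factor(anchor, matrix)
puf = opuf.anchor_matrix(matrix, a, anchor)
print("anchoring factor a:", round(a, 4))
for code in ("11111", "51255", "12345", "55555"):
    print(f"V({code}) =", round(puf.value(code), 4))
```

prints

```
scaled value of 12345: 0.5657
anchoring factor a: 1.378
V(11111) = 1.0
V(51255) = 0.0
V(12345) = 0.4016
V(55555) = -0.378
```

Before anchoring, `12345` keeps 0.5657 of the 1–0 scale. Anchoring forces
the equal-to-dead state `51255` to 0 while full health stays at 1; the
worst state ends up at −0.378, i.e. worse than being dead for this
respondent, whose utility range is a = 1.378.

The same pipeline runs from the shell:

```sh
opuf simulate --n 50 --seed 1 --out respondents.csv --latents latents.json
opuf construct --respondents respondents.csv --out-dir valuesets/
opuf aggregate --valuesets valuesets/ --out tariff.csv
opuf validate  --respondents respondents.csv --out report.json
opuf export    --tariff tariff.csv --out all_state_values.csv
```

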