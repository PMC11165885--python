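# Methods

## Model and procedure

The engine implements a semi-quantitative MCDA pipeline for joint One
Health prioritisation of risk factors and epidemic-prone diseases. Its
core assumptions:

* The two streams are independent: risks and diseases are shortlisted,
  weighted, scored and ranked separately, with identical machinery.
* A *risk* decomposes into likelihood × impact: three likelihood
  criteria (scope of exposure, frequency of exposure, mitigation
  strategy) enter an AHP-weighted sum; the impact criterion (potential
  for outbreak) multiplies it unweighted. A *disease threat*
  decomposes analogously into four threat criteria (severity,
  prevalence, transmissibility, preventive/control strategy) and the
  disease-burden multiplier.
* Criterion scores are group-consensus ordinals in {1, 2, 3} against a
  fixed rubric. The rubric direction is uniform — larger is worse —
  which makes the strategy criteria counterintuitive (3 = *no* strategy
  available); this is deliberate so the composite is monotone in every
  input.
* Groups stay separate through ranking: no consensus judgment matrix
  and no inter-group score reconciliation. Aggregation happens only at
  the last stage, on normalised scores.

### Selection

Include votes are summed per candidate; abstention counts as exclusion
(all votes weigh equally). The top-k cut keeps every candidate tied at
the k-th count, flags the tie, and leaves trimming to the moderators —
an engine must never silently drop a tied candidate from a live
workshop. Only candidates with at least one vote are eligible.

### AHP weighting

Only the upper triangle of each judgment matrix is elicited (3 or 6
judgments); diagonal and reciprocal cells are derived. Entries are kept
as exact rationals so reciprocity a_ij·a_ji = 1 holds exactly, not to
float tolerance. Admissible values are integers 1–9 and exact
reciprocals 1/2–1/9; intermediate values (9.5, 2/3) are rejected.

Weight extraction defaults to the principal right eigenvector (power
iteration, tolerance 1e−12, capped at 10,000 iterations — convergence
is guaranteed for positive matrices by Perron–Frobenius; the cap is a
guard). The row-geometric-mean method is available by flag; the two
agree on every consistent matrix, which the test suite exploits as a
cross-check together with `numpy.linalg.eig` as an independent oracle.

λ_max is estimated as the row-mean of (A·w)/w, CI = (λ_max − n)/(n−1),
CR = CI/RI(n) with the standard random-index table (RI(3) = 0.58,
RI(4) = 0.90; Saaty's simulated values), overridable by the caller.
CR > 0.10 produces a prominent warning but does not stop the pipeline:
workshops resolve inconsistency by consensus, and hard-failing would
block a live session. `--strict-consistency` upgrades the flag to an
error for offline re-analysis.

### Composite scores and ranking

Composites are computed at full float precision; rounding (4 decimals)
happens only in presentation. Bounds follow from the construction:
weights sum to 1 and scores lie in [1, 3], so the weighted sum is in
[1, 3] and the composite in [1, 9], attaining the endpoints only when
every input is 1 (resp. 3).

Min-max normalisation maps each group's best item to 1 and worst to 0.
A degenerate group (all composites equal) yields all-zero normalised
scores plus an explicit flag rather than an error; the flag matters
because 0 does not mean "lowest priority" there. Ranking is
competition-style ("1, 1, 3") so ties stay visible; tie detection
rounds to 9 decimals, which cannot conflate genuinely different inputs
on a 1–3 score scale with ≤ 5 groups, but absorbs float noise from the
weighted sums. Manual overrides may only touch reported tie sets and
must leave a valid competition ranking; they are recorded as audit
notes in the output table.

The combined cross-group rank uses the arithmetic mean of per-group
normalised scores, then the same ranking rule. The combination rule is
a package default (labelled in the output as `mean-normalised`): it is
the least-structured choice consistent with per-group normalised
columns, and the method field leaves room for alternatives such as
Borda counts on group ranks without changing file formats.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `catalogue_limit` | 50 per stream | intake hard cap |
| groups | ≤ 5 (error above) | independent scoring panels |
| participants per group | 5–7 advisory band | outside → warning only, because published guidance is itself inconsistent ("five to six" vs "maximum of 6–7") |
| shortlist size k | 10 | requested cutoff; output may exceed it on ties |
| weight method | eigenvector | `geometric-mean` by flag |
| CR threshold | 0.10 | flag, not failure; strict mode errors |
| power iteration | tol 1e−12, ≤ 10,000 iter | eigenvector extraction |
| tie rounding | 9 decimals | tie detection on normalised scores |
| float storage | 17 significant digits | CSV round-trips IEEE doubles exactly |

## Synthetic workshops

`SimulationSpec` defaults describe the intended study conditions: 25
participants in 5 groups, 30 candidates per stream, shortlist 10,
judgment noise 0.1 (log-scale s.d.), uniform score distribution over
{1, 2, 3}. True weights default to risk 4:2:1 and disease 8:4:2:1 —
scale-representable ratios, so noise-free judgments snap exactly to a
consistent matrix and AHP recovers the weights to machine precision
(the parameter-recovery test). Judgment noise is multiplicative:
a_ij = (w_i/w_j)·exp(ε), ε ~ N(0, σ), snapped to the nearest scale
value in log-space with ties toward 1 (the scale is multiplicative, so
log distance is the natural metric; snapping toward 1 is the
conservative judgment). Votes use a per-item inclusion probability
drawn uniformly from [0.1, 0.9] unless specified, which gives separated
vote totals without degenerate unanimity.

The generator emulates file-level completeness and statistical control,
not workshop behaviour: no consensus dynamics, no sector-correlated
voting, and scores i.i.d. across groups unless the `score_correlation`
knob routes a shared per-item latent score through all groups. Passing
tests therefore demonstrate the *engine's* correctness and the AHP
stage's noise response — not that real stakeholder panels behave like
the generator.

`recover_weights_experiment` repeats generate → expand → solve and
reports the mean absolute weight error and CR distribution; MAE is 0 at
noise 0 and grows with noise (checked at σ = 0, 0.05, 0.2 with 200
replicates — sizes chosen to keep the whole suite fast while making the
orderings stable across seeds).

## Numerical and degenerate-input choices

* Reciprocals are exact `Fraction`s end to end; floats appear only at
  eigen-extraction.
* Empty score group → error; degenerate group → flagged zeros (see
  above); k larger than the voted pool → warning and all voted items.
* n < 3 criteria: CR is reported as 0 with a note (RI(2) = 0 makes the
  ratio undefined); the structural validator normally prevents this
  case.
* Pipeline determinism: no randomness outside the generator; output
  CSVs store floats at 17 significant digits so reruns are
  byte-identical and reads reproduce stored doubles exactly (readers
  should use round-trip float parsing).

## Known limitations

* The combined-rank rule is a documented default, not an elicited one;
  rank-based aggregation alternatives are not yet implemented.
* No inter-group agreement statistics (e.g. Kendall's W).
* No incomplete-judgment completion; every pair must be elicited.
* The spreadsheet export is one-way; the engine never reads
  spreadsheets back, to avoid formula/locale drift.
* Severity rubric bands referring to "one or both sectors" leave the
  mixed-band case to the scoring group; the engine records the chosen
  ordinal only.
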