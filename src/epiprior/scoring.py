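"""Ordinal score validation and composite scores (workshop steps 3–4).

Each group assigns every shortlisted item an integer score 1–3 on each
criterion of its stream. The composite collapses these into a single
number per item per group:

    composite = (Σ_c score_c · w_c) × multiplier_score

where the sum runs over the stream's weighted criteria (likelihood
criteria for risks, threat criteria for diseases), w are the group's AHP
weights, and the multiplier is the raw 1–3 score on the stream's
unweighted impact/outcome criterion (potential for outbreak, resp.
disease burden). Because scores lie in [1,3] and weights sum to 1, the
weighted sum lies in [1,3] and the composite in [1,9].

The multiplier criterion deliberately takes no weight and no part in the
pairwise comparisons — it multiplies the weighted sum directly.
Half-points and abstentions are rejected: each group must reach one
integer consensus score per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ahp import WeightVector
from .core import Criterion, OrdinalScore, ValidationReport, \
    multiplier_criterion, weighted_criteria
from .selection import Shortlist

VALID_SCORES = (1, 2, 3)


@dataclass(frozen=True)
class CompositeScore:
    item: str
    group: str
    stream: str
    weighted_sum: float
    multiplier: int
    value: float


def validate_scores(sheet: list[OrdinalScore], shortlist: Shortlist,
                    criteria: list[Criterion], groups: list[str],
                    stream: str) -> ValidationReport:
    """Check the score sheet for completeness and range.

    Errors: missing (item, criterion, group) cell; value outside {1,2,3};
    score for an item not on the shortlist; duplicate cell. Findings are
    returned, never raised.
    """
    rep = ValidationReport()
    stream_criteria = [c.id for c in criteria if c.stream == stream]
    items = set(shortlist.items)
    cells: set[tuple[str, str, str]] = set()
    for s in sheet:
        key = (s.item, s.criterion, s.group)
        if key in cells:
            rep.errors.append(
                f"duplicate score for item '{s.item}', criterion "
                f"'{s.criterion}', group '{s.group}'"
            )
        cells.add(key)
        if s.item not in items:
            rep.errors.append(
                f"score for item '{s.item}' not on the {stream} shortlist "
                f"(group '{s.group}')"
            )
        if s.criterion not in stream_criteria:
            rep.errors.append(
                f"score for unknown criterion '{s.criterion}' "
                f"(item '{s.item}', group '{s.group}')"
            )
        if s.value not in VALID_SCORES:
            rep.errors.append(
                f"score {s.value} outside 1-3 for item '{s.item}', "
                f"criterion '{s.criterion}', group '{s.group}'"
            )
    for g in groups:
        for item in shortlist.items:
            for crit in stream_criteria:
                if (item, crit, g) not in cells:
                    rep.errors.append(
                        f"missing score for item '{item}', criterion "
                        f"'{crit}', group '{g}'"
                    )
    return rep


def composite_score(scores: dict[str, int], weights: WeightVector,
                    multiplier: int, item: str, group: str,
                    stream: str) -> CompositeScore:
    """Weighted sum of criterion scores times the 1–3 multiplier."""
    if set(scores) != set(weights.criteria):
        raise ValueError(
            f"item '{item}' (group '{group}'): scored criteria "
            f"{sorted(scores)} do not match weighted criteria "
            f"{sorted(weights.criteria)}"
        )
    for crit, v in scores.items():
        if v not in VALID_SCORES:
            raise ValueError(
                f"item '{item}': score {v} on '{crit}' outside 1-3"
            )
    if multiplier not in VALID_SCORES:
        raise ValueError(f"item '{item}': multiplier {multiplier} outside 1-3")
    wmap = weights.as_dict()
    wsum = sum(scores[c] * wmap[c] for c in weights.criteria)
    return CompositeScore(item, group, stream, wsum, multiplier,
                          wsum * multiplier)


def risk_impact_score(scores: dict[str, int], weights: WeightVector,
                      outbreak_potential: int, item: str = "",
                      group: str = "") -> CompositeScore:
    """Risk impact score: weighted likelihood sum × outbreak-potential score."""
    return composite_score(scores, weights, outbreak_potential,
                           item, group, "risk")


def disease_burden_score(scores: dict[str, int], weights: WeightVector,
                         burden: int, item: str = "",
                         group: str = "") -> CompositeScore:
    """Disease burden score: weighted threat sum × disease-burden score."""
    return composite_score(scores, weights, burden, item, group, "disease")


def compute_composites(sheet: list[OrdinalScore], shortlist: Shortlist,
                       criteria: list[Criterion],
                       weights_by_group: dict[str, WeightVector],
                       stream: str) -> list[CompositeScore]:
    """Composite scores for every shortlisted item in every group."""
    mult = multiplier_criterion(criteria, stream)
    wcrit = [c.id for c in weighted_criteria(criteria, stream)]
    by_cell = {(s.item, s.criterion, s.group): s.value for s in sheet}
    out: list[CompositeScore] = []
    for group, wv in weights_by_group.items():
        for item in shortlist.items:
            try:
                scores = {c: by_cell[(item, c, group)] for c in wcrit}
                m = by_cell[(item, mult.id, group)]
            except KeyError as exc:
                raise ValueError(
                    f"missing score cell {exc.args[0]} — run score "
                    "validation first"
                ) from exc
            out.append(composite_score(scores, wv, m, item, group, stream))
    return out
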