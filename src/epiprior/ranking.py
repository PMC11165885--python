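"""Normalisation and ranking (workshop step 5).

Composite scores are min-max normalised within each group,

    normalised = (value − min) / (max − min),

so each group's best item scores 1 and its worst 0. When every composite
in a group is equal (max == min) the group is *degenerate*: all
normalised scores are set to 0 and the group is flagged — 0 must not be
read as "lowest priority" there.

Ranks are competition ranks (descending; tied items share the smallest
applicable rank, the next rank is skipped: 1, 1, 3). Ties are detected
after rounding to 9 decimals and always reported, never broken by the
engine — resolving them is a stakeholder-consensus decision, supported
by explicit manual overrides.

The combined cross-group rank is computed, by default, from the
arithmetic mean of each item's per-group normalised scores (a package
default; the combination rule is configurable in principle and is
labelled in the output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TIE_DECIMALS = 9


@dataclass
class RankingTable:
    stream: str
    groups: list[str]
    composites: dict[str, dict[str, float]]   # group -> item -> composite
    normalised: dict[str, dict[str, float]]   # group -> item -> [0,1]
    group_ranks: dict[str, dict[str, int]]    # group -> item -> rank
    group_ties: dict[str, list[frozenset[str]]]
    degenerate: dict[str, bool]               # group -> all-equal flag
    combined_score: dict[str, float]          # item -> mean normalised
    combined_rank: dict[str, int]
    combined_ties: list[frozenset[str]]
    combined_method: str = "mean-normalised"
    overrides_audit: dict[str, str] = field(default_factory=dict)

    @property
    def items(self) -> list[str]:
        return sorted(self.combined_score)


def normalise(values: dict[str, float]) -> tuple[dict[str, float], bool]:
    """Min-max normalise one group's composites; returns (scores, degenerate)."""
    if not values:
        raise ValueError("cannot normalise an empty group")
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {item: 0.0 for item in values}, True
    return {item: (v - lo) / (hi - lo) for item, v in values.items()}, False


def rank_within_group(normalised: dict[str, float]
                      ) -> tuple[dict[str, int], list[frozenset[str]]]:
    """Descending competition ranks with explicit tie sets.

    Equality is judged after rounding scores to 9 decimals; composites
    are short products of small rationals, so this cannot conflate
    genuinely different score sheets.
    """
    rounded = {item: round(s, TIE_DECIMALS) for item, s in normalised.items()}
    by_score: dict[float, list[str]] = {}
    for item, s in rounded.items():
        by_score.setdefault(s, []).append(item)
    ranks: dict[str, int] = {}
    ties: list[frozenset[str]] = []
    position = 1
    for score in sorted(by_score, reverse=True):
        members = sorted(by_score[score])
        for item in members:
            ranks[item] = position
        if len(members) > 1:
            ties.append(frozenset(members))
        position += len(members)
    return ranks, ties


def combined_rank(per_group_normalised: dict[str, dict[str, float]],
                  method: str = "mean-normalised"
                  ) -> tuple[dict[str, float], dict[str, int],
                             list[frozenset[str]]]:
    """Cross-group score (mean of normalised scores) and its ranking.

    Every item must appear in every group; incomplete sheets are an
    error listing the missing (item, group) pairs.
    """
    if method != "mean-normalised":
        raise ValueError(f"unknown combined-rank method '{method}'")
    if not per_group_normalised:
        raise ValueError("no groups to combine")
    all_items: set[str] = set()
    for scores in per_group_normalised.values():
        all_items.update(scores)
    missing = [(item, g) for g, scores in per_group_normalised.items()
               for item in sorted(all_items) if item not in scores]
    if missing:
        raise ValueError(f"items missing from groups: {missing}")
    n_groups = len(per_group_normalised)
    combined = {
        item: sum(scores[item] for scores in per_group_normalised.values())
        / n_groups
        for item in all_items
    }
    ranks, ties = rank_within_group(combined)
    return combined, ranks, ties


def build_ranking_table(composites: dict[str, dict[str, float]], stream: str,
                        method: str = "mean-normalised") -> RankingTable:
    """Full step-5 table from per-group composite scores."""
    groups = sorted(composites)
    norm: dict[str, dict[str, float]] = {}
    degenerate: dict[str, bool] = {}
    group_ranks: dict[str, dict[str, int]] = {}
    group_ties: dict[str, list[frozenset[str]]] = {}
    for g in groups:
        norm[g], degenerate[g] = normalise(composites[g])
        group_ranks[g], group_ties[g] = rank_within_group(norm[g])
    combined, ranks, ties = combined_rank(norm, method)
    return RankingTable(stream, groups, composites, norm, group_ranks,
                        group_ties, degenerate, combined, ranks, ties,
                        combined_method=method)


def _is_valid_competition_ranking(ranks: dict[str, int]) -> bool:
    values = sorted(ranks.values())
    n_smaller = 0
    for rank, group in _groupby_sorted(values):
        if rank != n_smaller + 1:
            return False
        n_smaller += len(group)
    return True


def _groupby_sorted(values: list[int]):
    out: dict[int, list[int]] = {}
    for v in values:
        out.setdefault(v, []).append(v)
    return sorted(out.items())


def apply_manual_overrides(table: RankingTable,
                           overrides: dict[str, int]) -> RankingTable:
    """Resolve combined-rank ties by stakeholder consensus.

    Overrides may touch only items inside reported combined tie sets, and
    the resulting rank assignment must remain a valid competition ranking
    (e.g. a tie {A, B} at rank 1 may become A→1, B→2, but not both→2,
    which would leave rank 1 unoccupied). Overridden items carry an audit
    note in the returned table; the input table is not modified.
    """
    tied_items = {item for ts in table.combined_ties for item in ts}
    for item in overrides:
        if item not in table.combined_rank:
            raise ValueError(f"override for unknown item '{item}'")
        if item not in tied_items:
            raise ValueError(
                f"override for item '{item}' which is not in any tie set"
            )
    new_ranks = dict(table.combined_rank)
    new_ranks.update(overrides)
    if not _is_valid_competition_ranking(new_ranks):
        raise ValueError(
            f"overrides {overrides} do not yield a valid competition ranking"
        )
    audit = dict(table.overrides_audit)
    for item, rank in overrides.items():
        audit[item] = (
            f"rank manually set to {rank} (was {table.combined_rank[item]}, "
            "tie resolved by consensus)"
        )
    remaining = [ts for ts in table.combined_ties
                 if len({new_ranks[i] for i in ts}) == 1]
    return RankingTable(
        table.stream, table.groups, table.composites, table.normalised,
        table.group_ranks, table.group_ties, table.degenerate,
        table.combined_score, new_ranks, remaining,
        combined_method=table.combined_method, overrides_audit=audit,
    )
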