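"""Vote tallying and shortlist selection (step 1 of the workshop).

Every participant casts an include/exclude vote per candidate; candidates
are shortlisted by total include votes. Ties at the cutoff are never
broken silently: all tied candidates enter the shortlist and the tie is
flagged, so the moderators can trim by consensus (or rerun with larger k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import CandidateItem


@dataclass(frozen=True)
class VoteRecord:
    participant: str
    item: str
    include: bool


@dataclass
class Shortlist:
    stream: str
    entries: list[tuple[str, int]]  # (item id, vote count), sorted
    cutoff: int
    tie_at_cutoff: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def items(self) -> list[str]:
        return [item for item, _ in self.entries]


def tally_votes(votes: list[VoteRecord],
                catalogue: list[CandidateItem]) -> dict[str, int]:
    """Count include votes per catalogue item.

    Items never voted on appear with count 0; abstention (missing record)
    counts as exclusion. Raises on votes for unknown items or duplicate
    (participant, item) records.
    """
    counts: dict[str, int] = {c.id: 0 for c in catalogue}
    seen: set[tuple[str, str]] = set()
    for v in votes:
        if v.item not in counts:
            raise ValueError(f"vote references unknown item '{v.item}'")
        key = (v.participant, v.item)
        if key in seen:
            raise ValueError(
                f"duplicate vote by participant '{v.participant}' on item '{v.item}'"
            )
        seen.add(key)
        if v.include:
            counts[v.item] += 1
    return counts


def select_top(counts: dict[str, int], k: int, stream: str = "risk") -> Shortlist:
    """Shortlist the k highest-voted items, keeping all items tied at the cutoff.

    Only items with at least one include vote are eligible. The shortlist
    may exceed ``k`` when the k-th count is tied; ``tie_at_cutoff`` is set
    in that case. Ordering is deterministic: vote count descending, then
    item id ascending.
    """
    if k < 1:
        raise ValueError(f"shortlist size k must be >= 1, got {k}")
    voted = sorted(
        ((item, n) for item, n in counts.items() if n > 0),
        key=lambda e: (-e[1], e[0]),
    )
    warnings: list[str] = []
    if k >= len(voted):
        if k > len(voted):
            warnings.append(
                f"requested shortlist size {k} exceeds the {len(voted)} "
                "item(s) with at least one vote; returning all voted items"
            )
        return Shortlist(stream, voted, k, tie_at_cutoff=False, warnings=warnings)
    cut_count = voted[k - 1][1]
    entries = [e for e in voted if e[1] >= cut_count]
    return Shortlist(stream, entries, k,
                     tie_at_cutoff=len(entries) > k, warnings=warnings)
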