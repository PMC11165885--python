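"""Domain types and intake validation for a prioritisation workshop.

A workshop prioritises two independent *streams* of candidates:

* ``risk`` — risk factors for disease emergence, scored on three weighted
  *likelihood* criteria (scope of exposure, frequency of exposure,
  mitigation strategy) and one unweighted *impact* multiplier (potential
  for outbreak);
* ``disease`` — epidemic-prone diseases, scored on four weighted *threat*
  criteria (severity, prevalence, transmissibility, preventive and control
  strategy) and one unweighted *outcome* multiplier (disease burden).

Each criterion carries a three-level ordinal rubric mapped to scores 1–3.
Criteria are data, not code: the defaults below can be replaced from a
criteria catalogue file so the dimensions can be adapted to a local
context, but the structural shape (3+1 weighted/multiplier criteria for
risks, 4+1 for diseases) is enforced unless explicitly overridden.

Note on directionality: for the two "strategy" criteria a score of 3 means
*no* strategy is available — larger is always riskier/worse, so composites
are comparable across criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STREAMS = ("risk", "disease")

#: required number of weighted criteria per stream
WEIGHTED_CRITERIA_COUNT = {"risk": 3, "disease": 4}

#: intake limits: candidates per stream and groups per workshop
CATALOGUE_LIMIT = 50
MAX_GROUPS = 5

#: advisory band for participants per group (outside => warning, not error)
GROUP_SIZE_BAND = (5, 7)


@dataclass(frozen=True)
class RubricLevel:
    score: int
    description: str


@dataclass(frozen=True)
class Criterion:
    """A named scoring dimension with its 3-level ordinal rubric.

    ``role`` is ``"weighted"`` for criteria entering the AHP-weighted sum
    and ``"multiplier"`` for the single unweighted 1–3 multiplier of the
    stream (potential for outbreak / disease burden).
    """

    id: str
    label: str
    stream: str
    role: str  # "weighted" | "multiplier"
    rubric: tuple[RubricLevel, ...]


@dataclass(frozen=True)
class CandidateItem:
    id: str
    label: str
    stream: str
    source: str = "catalogue"  # "catalogue" | "participant-added"


@dataclass
class WorkshopConfig:
    groups: list[str]
    participants_per_group: int = 5
    shortlist_size_risk: int = 10
    shortlist_size_disease: int = 10
    catalogue_limit: int = CATALOGUE_LIMIT
    tie_policy: str = "report"  # "report" | "manual-override"
    combined_rank_method: str = "mean-normalised"
    allow_custom_criteria: bool = False


@dataclass(frozen=True)
class OrdinalScore:
    """One group's consensus score (1–3) for one item on one criterion."""

    item: str
    criterion: str
    group: str
    value: int


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)


def default_criteria() -> list[Criterion]:
    """The default criterion catalogue for both streams."""

    def levels(*descs: str) -> tuple[RubricLevel, ...]:
        return tuple(RubricLevel(i + 1, d) for i, d in enumerate(descs))

    return [
        Criterion(
            "scope", "Scope of exposure", "risk", "weighted",
            levels(
                "Less than 20% of the population exposed",
                "20-50% of the population exposed",
                "More than 50% of the population exposed",
            ),
        ),
        Criterion(
            "freq", "Frequency of exposure", "risk", "weighted",
            levels("Improbable", "Occasional", "Frequent"),
        ),
        Criterion(
            "mitig", "Mitigation strategy", "risk", "weighted",
            levels(
                "Strategy available (policy/norms/regulations or similar)",
                "Strategy available (guidelines/communication material or similar)",
                "No strategy available",
            ),
        ),
        Criterion(
            "outbreak", "Potential for outbreak", "risk", "multiplier",
            levels("Low", "Medium", "High"),
        ),
        Criterion(
            "severity", "Severity", "disease", "weighted",
            levels(
                "CFR below 5% in one or both sectors",
                "CFR 5-15% in one or both sectors",
                "CFR 15% or more in one or both sectors",
            ),
        ),
        Criterion(
            "prevalence", "Prevalence", "disease", "weighted",
            levels(
                "Below 1 per 100,000 population",
                "1-100 per 100,000 population",
                "Above 100 per 100,000 population",
            ),
        ),
        Criterion(
            "transmissibility", "Transmissibility", "disease", "weighted",
            levels(
                "No epidemic, or more than 10 years ago",
                "Epidemic within the past 5-10 years",
                "Epidemic within the past 5 years",
            ),
        ),
        Criterion(
            "strategy", "Preventive and control strategy", "disease", "weighted",
            levels(
                "Available for animals and humans",
                "Available for animals or humans",
                "Not available for animals and humans",
            ),
        ),
        Criterion(
            "burden", "Disease burden", "disease", "multiplier",
            levels(
                "No high burden in either sector",
                "High human DALY burden or high animal economic loss",
                "High human DALY burden and high animal economic loss",
            ),
        ),
    ]


def weighted_criteria(criteria: list[Criterion], stream: str) -> list[Criterion]:
    return [c for c in criteria if c.stream == stream and c.role == "weighted"]


def multiplier_criterion(criteria: list[Criterion], stream: str) -> Criterion:
    found = [c for c in criteria if c.stream == stream and c.role == "multiplier"]
    if len(found) != 1:
        raise ValueError(
            f"stream '{stream}' must have exactly one multiplier criterion, "
            f"found {len(found)}"
        )
    return found[0]


def _validate_criteria(criteria: list[Criterion],
                       allow_custom: bool) -> ValidationReport:
    rep = ValidationReport()
    seen: set[tuple[str, str]] = set()
    for c in criteria:
        key = (c.stream, c.id)
        if key in seen:
            rep.errors.append(f"criterion '{c.id}': duplicate id in stream '{c.stream}'")
        seen.add(key)
        if c.stream not in STREAMS:
            rep.errors.append(f"criterion '{c.id}': unknown stream '{c.stream}'")
            continue
        if c.role not in ("weighted", "multiplier"):
            rep.errors.append(f"criterion '{c.id}': unknown role '{c.role}'")
        if len(c.rubric) != 3 or [l.score for l in c.rubric] != [1, 2, 3]:
            rep.errors.append(
                f"criterion '{c.id}': rubric must have exactly 3 levels scored 1,2,3"
            )
        elif any(not l.description.strip() for l in c.rubric):
            rep.errors.append(f"criterion '{c.id}': empty rubric level description")
    for stream in STREAMS:
        mults = [c for c in criteria if c.stream == stream and c.role == "multiplier"]
        if len(mults) != 1:
            rep.errors.append(
                f"stream '{stream}': exactly one multiplier criterion required, "
                f"found {len(mults)}"
            )
        n_weighted = len(weighted_criteria(criteria, stream))
        expected = WEIGHTED_CRITERIA_COUNT[stream]
        if n_weighted != expected and not allow_custom:
            rep.errors.append(
                f"stream '{stream}': {expected} weighted criteria required, "
                f"found {n_weighted}"
            )
    return rep


def validate_workshop(config: WorkshopConfig,
                      criteria: list[Criterion],
                      catalogue: list[CandidateItem]) -> ValidationReport:
    """Validate workshop structure; returns findings, never raises.

    Errors: more than 5 groups, catalogue over the per-stream cap,
    duplicate candidate ids, malformed criteria. Group sizes outside the
    5–7 band are warnings only (the advisory bounds are soft).
    """
    rep = ValidationReport()

    n_groups = len(config.groups)
    if n_groups < 1:
        rep.errors.append("config: at least one group required")
    if n_groups > MAX_GROUPS:
        rep.errors.append(
            f"config: {n_groups} groups exceed the maximum of {MAX_GROUPS}"
        )
    if len(set(config.groups)) != n_groups:
        dupes = sorted({g for g in config.groups if config.groups.count(g) > 1})
        rep.errors.append(f"config: duplicate group ids {dupes}")

    lo, hi = GROUP_SIZE_BAND
    if not lo <= config.participants_per_group <= hi:
        rep.warnings.append(
            f"config: {config.participants_per_group} participants per group "
            f"outside the advised {lo}-{hi} band"
        )

    rep.extend(_validate_criteria(criteria, config.allow_custom_criteria))

    for stream in STREAMS:
        items = [c for c in catalogue if c.stream == stream]
        if len(items) > config.catalogue_limit:
            rep.errors.append(
                f"catalogue: stream '{stream}' has {len(items)} candidates, "
                f"limit is {config.catalogue_limit}"
            )
        seen_ids: set[str] = set()
        for it in items:
            if it.id in seen_ids:
                rep.errors.append(
                    f"candidate '{it.id}': duplicate id in stream '{stream}'"
                )
            seen_ids.add(it.id)
            if it.source not in ("catalogue", "participant-added"):
                rep.errors.append(
                    f"candidate '{it.id}': unknown source '{it.source}'"
                )
    for it in catalogue:
        if it.stream not in STREAMS:
            rep.errors.append(f"candidate '{it.id}': unknown stream '{it.stream}'")

    # participant-added items do not bypass the cap; surface the situation
    added = [c for c in catalogue if c.source == "participant-added"]
    if added:
        rep.warnings.append(
            f"catalogue: {len(added)} participant-added item(s) counted "
            "against the per-stream limit"
        )
    return rep
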