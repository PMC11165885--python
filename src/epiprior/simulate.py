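"""Synthetic workshop generator and weight-recovery harness.

Emulates a full co-creation workshop so every pipeline stage can be
exercised without real elicitation data:

* a candidate catalogue per stream;
* per-participant include/exclude votes (Bernoulli per item, with a
  per-item "enthusiasm" probability so vote totals separate);
* per-group pairwise judgments generated from known true criterion
  weights: a_ij = (w_i/w_j)·exp(ε), ε ~ Normal(0, judgment_noise) on the
  log scale, then snapped to the nearest admissible scale value (nearest
  in log-space — the scale is multiplicative — with ties broken toward
  1, i.e. toward the more conservative judgment);
* per-group ordinal score sheets drawn from a per-criterion distribution
  over {1,2,3}, with an optional agreement knob: with probability
  ``score_correlation`` a group reports the item's shared latent score
  instead of an independent draw, emulating inter-group agreement.

A single seeded NumPy generator drives all draws in a fixed order, so a
bundle is reproducible from the spec alone. What this emulates — and
what it does not: groups are independent scorers with no consensus
dynamics, and votes are exchangeable across participants; real
workshops have structured disagreement the generator does not model.

Defaults mirror a realistic workshop: 5 groups of 5, 25 participants,
30 candidates per stream, shortlists of 10, and scale-representable
true weights (risk 4:2:1, disease 8:4:2:1 — successive ratios on the
judgment scale) so that noise-free judgments recover the weights
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import ahp
from .core import (CandidateItem, Criterion, OrdinalScore, WorkshopConfig,
                   default_criteria, multiplier_criterion, weighted_criteria)
from .selection import VoteRecord, select_top, tally_votes

DEFAULT_TRUE_WEIGHTS = {
    "risk": (4 / 7, 2 / 7, 1 / 7),
    "disease": (8 / 15, 4 / 15, 2 / 15, 1 / 15),
}

_LOG_SCALE = np.array([math.log(float(v)) for v in ahp.SCALE])


@dataclass
class SimulationSpec:
    seed: int = 0
    n_risk_candidates: int = 30
    n_disease_candidates: int = 30
    n_participants: int = 25
    n_groups: int = 5
    shortlist_size: int = 10
    true_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v)
                                 for k, v in DEFAULT_TRUE_WEIGHTS.items()})
    judgment_noise: float = 0.1
    score_distribution: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    score_correlation: float = 0.0
    vote_enthusiasm: dict[str, float] | None = None  # item id -> P(include)

    def validate(self) -> None:
        if self.n_risk_candidates > 50 or self.n_disease_candidates > 50:
            raise ValueError("candidate counts must be <= 50 per stream")
        if not 1 <= self.n_groups <= 5:
            raise ValueError("group count must be 1-5")
        if self.judgment_noise < 0:
            raise ValueError("judgment_noise must be >= 0")
        for stream, w in self.true_weights.items():
            if any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(
                    f"true weights for '{stream}' must be positive and sum to 1"
                )
        if abs(sum(self.score_distribution) - 1.0) > 1e-9:
            raise ValueError("score_distribution must sum to 1")
        if not 0.0 <= self.score_correlation <= 1.0:
            raise ValueError("score_correlation must be in [0, 1]")


def snap_to_scale(ratio: float) -> Fraction:
    """Nearest admissible judgment value in log-space; ties toward 1."""
    if ratio <= 0:
        raise ValueError("judgment ratio must be positive")
    dist = np.abs(_LOG_SCALE - math.log(ratio))
    best = dist.min()
    # among values within float tolerance of the minimum, prefer closer to 1
    candidates = [ahp.SCALE[i] for i in np.flatnonzero(dist <= best + 1e-12)]
    return min(candidates, key=lambda v: (abs(math.log(float(v))), float(v)))


def simulate_judgments(true_w: tuple[float, ...], criteria: list[str],
                       noise: float, rng: np.random.Generator,
                       group: str, stream: str) -> ahp.JudgmentSet:
    judgments: dict[tuple[str, str], Fraction] = {}
    for i in range(len(criteria)):
        for j in range(i + 1, len(criteria)):
            ratio = true_w[i] / true_w[j]
            if noise > 0:
                ratio *= math.exp(rng.normal(0.0, noise))
            judgments[(criteria[i], criteria[j])] = snap_to_scale(ratio)
    return ahp.JudgmentSet(group, stream, judgments)


@dataclass
class SimulatedBundle:
    """Inputs of a complete synthetic workshop (pre-pipeline)."""

    spec: SimulationSpec
    config: WorkshopConfig
    criteria: list[Criterion]
    catalogue: list[CandidateItem]
    votes: list[VoteRecord]
    judgments: list[ahp.JudgmentSet]
    scores: list[OrdinalScore]


_RISK_NAMES = [
    "Unregulated live-animal markets", "Backyard poultry contact",
    "Open carcass disposal", "Untreated abattoir effluent",
    "Wildlife habitat encroachment", "Stray dog density",
    "Raw milk consumption", "Antibiotic misuse in livestock",
    "Poor farm biosecurity", "Rodent infestation of grain stores",
]

_DISEASE_NAMES = [
    "Rabies", "Brucellosis", "Leptospirosis", "Anthrax",
    "Avian influenza", "Crimean-Congo haemorrhagic fever", "Nipah virus",
    "Scrub typhus", "Japanese encephalitis", "Kyasanur forest disease",
]


def _candidate_label(stream: str, index: int) -> str:
    names = _RISK_NAMES if stream == "risk" else _DISEASE_NAMES
    if index < len(names):
        return names[index]
    kind = "risk factor" if stream == "risk" else "disease"
    return f"Candidate {kind} {index + 1}"


def generate_bundle(spec: SimulationSpec) -> SimulatedBundle:
    """Deterministically generate all workshop inputs from the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    criteria = default_criteria()
    groups = [f"G{i + 1}" for i in range(spec.n_groups)]
    config = WorkshopConfig(
        groups=groups,
        participants_per_group=max(1, spec.n_participants // spec.n_groups),
        shortlist_size_risk=spec.shortlist_size,
        shortlist_size_disease=spec.shortlist_size,
    )

    catalogue: list[CandidateItem] = []
    for stream, n in (("risk", spec.n_risk_candidates),
                      ("disease", spec.n_disease_candidates)):
        prefix = "RF" if stream == "risk" else "DZ"
        catalogue.extend(
            CandidateItem(f"{prefix}{i + 1:02d}", _candidate_label(stream, i),
                          stream)
            for i in range(n)
        )

    # votes: per-item enthusiasm, then Bernoulli per participant
    votes: list[VoteRecord] = []
    participants = [f"P{i + 1:02d}" for i in range(spec.n_participants)]
    for item in catalogue:
        if spec.vote_enthusiasm and item.id in spec.vote_enthusiasm:
            p = spec.vote_enthusiasm[item.id]
        else:
            p = rng.uniform(0.1, 0.9)
        draws = rng.random(spec.n_participants) < p
        votes.extend(VoteRecord(part, item.id, bool(inc))
                     for part, inc in zip(participants, draws))

    # judgments per group per stream from the true weights
    judgments: list[ahp.JudgmentSet] = []
    for group in groups:
        for stream in ("risk", "disease"):
            crit_ids = [c.id for c in weighted_criteria(criteria, stream)]
            judgments.append(
                simulate_judgments(spec.true_weights[stream], crit_ids,
                                   spec.judgment_noise, rng, group, stream)
            )

    # scores for shortlisted items only (scoring follows selection)
    scores: list[OrdinalScore] = []
    probs = np.asarray(spec.score_distribution)
    for stream in ("risk", "disease"):
        stream_cat = [c for c in catalogue if c.stream == stream]
        counts = tally_votes([v for v in votes
                              if v.item in {c.id for c in stream_cat}],
                             stream_cat)
        shortlist = select_top(counts, spec.shortlist_size, stream)
        crit_ids = ([c.id for c in weighted_criteria(criteria, stream)]
                    + [multiplier_criterion(criteria, stream).id])
        for item_id in shortlist.items:
            latent = {c: int(rng.choice((1, 2, 3), p=probs))
                      for c in crit_ids}
            for group in groups:
                for c in crit_ids:
                    if rng.random() < spec.score_correlation:
                        value = latent[c]
                    else:
                        value = int(rng.choice((1, 2, 3), p=probs))
                    scores.append(OrdinalScore(item_id, c, group, value))

    return SimulatedBundle(spec, config, criteria, catalogue, votes,
                           judgments, scores)


def recover_weights_experiment(spec: SimulationSpec, replicates: int,
                               stream: str = "risk",
                               method: str = "eigenvector") -> dict:
    """How well does AHP recover the true weights under judgment noise?

    Per replicate: simulate one judgment set from the true weights,
    expand and solve it, and record the per-criterion absolute error and
    the consistency ratio. Returns mean absolute error (overall and
    per-criterion), the CR distribution, and the fraction of replicates
    flagged CR > 0.1.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    criteria = [c.id for c in weighted_criteria(default_criteria(), stream)]
    true_w = np.asarray(spec.true_weights[stream])
    abs_errors = np.zeros((replicates, len(criteria)))
    crs = np.zeros(replicates)
    for r in range(replicates):
        jset = simulate_judgments(tuple(true_w), criteria,
                                  spec.judgment_noise, rng, f"rep{r}", stream)
        matrix = ahp.expand_matrix(jset, criteria)
        wv = ahp.compute_weights(matrix, method)
        abs_errors[r] = np.abs(wv.weights - true_w)
        crs[r] = wv.consistency_ratio
    return {
        "stream": stream,
        "replicates": replicates,
        "judgment_noise": spec.judgment_noise,
        "mae": float(abs_errors.mean()),
        "mae_per_criterion": dict(zip(criteria,
                                      abs_errors.mean(axis=0).tolist())),
        "cr_mean": float(crs.mean()),
        "cr_values": crs.tolist(),
        "flagged_fraction": float(np.mean(crs > ahp.CR_THRESHOLD)),
    }
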