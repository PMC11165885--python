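"""Workshop file formats, the pipeline driver and the summary report.

Canonical formats are plain comma-separated UTF-8 text with a header row
and "." decimals. A workshop lives in one directory:

* ``config.yaml`` — groups, shortlist sizes, policies (mandatory)
* ``criteria.csv`` — stream, id, label, role, level1..level3 (mandatory;
  omit to use the built-in default criteria)
* ``catalogue.csv`` — stream, id, label, source (mandatory)
* ``votes.csv`` — participant, stream, item, include(0/1)
* ``judgments.csv`` — group, stream, criterion_i, criterion_j, value
  (value an integer 1–9 or "1/k")
* ``scores.csv`` — group, stream, item, criterion, value

Pipeline outputs are written next to the inputs: per-stream shortlists,
the weights report, composites, per-stream ranking tables (wide format),
the plain-text/HTML report, and ``run_log.json`` recording each stage
with content hashes of its inputs so a run is auditable. The pipeline is
a DAG — votes → shortlist → {judgments → weights, scores} → composites →
ranking — and is fully deterministic: the same input files always yield
byte-identical outputs. A spreadsheet export mirroring the ranking
tables is available as a one-way convenience; it is never read back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ahp import (CR_THRESHOLD, JudgmentSet, WeightVector, compute_weights,
                  expand_matrix, format_judgment, parse_judgment)
from .core import (STREAMS, CandidateItem, Criterion, OrdinalScore,
                   RubricLevel, ValidationReport, WorkshopConfig,
                   default_criteria, validate_workshop, weighted_criteria)
from .ranking import RankingTable, build_ranking_table
from .scoring import CompositeScore, compute_composites, validate_scores
from .selection import Shortlist, VoteRecord, select_top, tally_votes

STAGES = ("shortlist", "weights", "scores", "composites", "ranking")

CONFIG_FILE = "config.yaml"
CRITERIA_FILE = "criteria.csv"
CATALOGUE_FILE = "catalogue.csv"
VOTES_FILE = "votes.csv"
JUDGMENTS_FILE = "judgments.csv"
SCORES_FILE = "scores.csv"
RUN_LOG_FILE = "run_log.json"

#: float storage format: 17 significant digits round-trip IEEE doubles exactly
FLOAT_FORMAT = "%.17g"


@dataclass
class WorkshopBundle:
    directory: Path
    config: WorkshopConfig
    criteria: list[Criterion]
    catalogue: list[CandidateItem]
    votes: list[VoteRecord] | None = None
    judgments: list[JudgmentSet] | None = None
    scores: list[OrdinalScore] | None = None
    shortlists: dict[str, Shortlist] = field(default_factory=dict)
    weights: dict[tuple[str, str], WeightVector] = field(default_factory=dict)
    composites: dict[str, list[CompositeScore]] = field(default_factory=dict)
    rankings: dict[str, RankingTable] = field(default_factory=dict)
    validation: ValidationReport = field(default_factory=ValidationReport)
    run_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------- readers

def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return df


def read_config(path: Path) -> WorkshopConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "groups" not in raw:
        raise ValueError(f"{path.name}: 'groups' is required")
    known = {f for f in WorkshopConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path.name}: unknown key(s) {sorted(unknown)}")
    return WorkshopConfig(**{k: raw[k] for k in raw})


def read_criteria(path: Path) -> list[Criterion]:
    df = _read_csv(path, ["stream", "id", "label", "role",
                          "level1", "level2", "level3"])
    out = []
    for _, row in df.iterrows():
        rubric = tuple(RubricLevel(i, row[f"level{i}"]) for i in (1, 2, 3))
        out.append(Criterion(row["id"], row["label"], row["stream"],
                             row["role"], rubric))
    return out


def read_catalogue(path: Path) -> list[CandidateItem]:
    df = _read_csv(path, ["stream", "id", "label"])
    source = df["source"] if "source" in df.columns else ["catalogue"] * len(df)
    return [CandidateItem(r["id"], r["label"], r["stream"], src)
            for (_, r), src in zip(df.iterrows(), source)]


def read_votes(path: Path) -> tuple[list[VoteRecord], ValidationReport]:
    df = _read_csv(path, ["participant", "stream", "item", "include"])
    rep = ValidationReport()
    votes = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["include"] not in ("0", "1"):
            rep.errors.append(
                f"{path.name}:{line}: include must be 0 or 1, "
                f"got '{row['include']}' (item '{row['item']}')"
            )
            continue
        votes.append(VoteRecord(row["participant"], row["item"],
                                row["include"] == "1"))
    return votes, rep


def read_judgments(path: Path) -> tuple[list[JudgmentSet], ValidationReport]:
    df = _read_csv(path, ["group", "stream", "criterion_i", "criterion_j",
                          "value"])
    rep = ValidationReport()
    sets: dict[tuple[str, str], JudgmentSet] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            value = parse_judgment(row["value"])
        except ValueError as exc:
            rep.errors.append(f"{path.name}:{line}: {exc}")
            continue
        key = (row["group"], row["stream"])
        jset = sets.setdefault(key, JudgmentSet(row["group"], row["stream"], {}))
        pair = (row["criterion_i"], row["criterion_j"])
        if pair in jset.judgments:
            rep.errors.append(
                f"{path.name}:{line}: duplicate judgment for pair {pair} "
                f"(group '{row['group']}')"
            )
        jset.judgments[pair] = value
    return list(sets.values()), rep


def read_scores(path: Path) -> tuple[list[OrdinalScore], ValidationReport]:
    df = _read_csv(path, ["group", "stream", "item", "criterion", "value"])
    rep = ValidationReport()
    scores = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            value = int(row["value"])
        except ValueError:
            rep.errors.append(
                f"{path.name}:{line}: score value '{row['value']}' is not "
                f"an integer (item '{row['item']}')"
            )
            continue
        scores.append(OrdinalScore(row["item"], row["criterion"],
                                   row["group"], value))
    return scores, rep


def load_bundle(directory: str | Path) -> WorkshopBundle:
    """Parse all present workshop files and validate cross-references.

    ``config.yaml``, ``criteria.csv`` and ``catalogue.csv`` are
    mandatory; stage inputs (votes, judgments, scores) are optional and
    simply marked absent. Malformed rows are reported with file and line
    number in the bundle's validation report.
    """
    directory = Path(directory)
    for name in (CONFIG_FILE, CRITERIA_FILE, CATALOGUE_FILE):
        if not (directory / name).exists():
            raise FileNotFoundError(
                f"mandatory workshop file missing: {directory / name}"
            )
    config = read_config(directory / CONFIG_FILE)
    criteria = read_criteria(directory / CRITERIA_FILE)
    catalogue = read_catalogue(directory / CATALOGUE_FILE)
    bundle = WorkshopBundle(directory, config, criteria, catalogue)
    bundle.validation = validate_workshop(config, criteria, catalogue)

    known_items = {c.id for c in catalogue}
    if (directory / VOTES_FILE).exists():
        bundle.votes, rep = read_votes(directory / VOTES_FILE)
        bundle.validation.extend(rep)
        for i, v in enumerate(bundle.votes):
            if v.item not in known_items:
                bundle.validation.errors.append(
                    f"{VOTES_FILE}: vote references unknown item '{v.item}'"
                )
    if (directory / JUDGMENTS_FILE).exists():
        bundle.judgments, rep = read_judgments(directory / JUDGMENTS_FILE)
        bundle.validation.extend(rep)
        for jset in bundle.judgments:
            if jset.group not in config.groups:
                bundle.validation.errors.append(
                    f"{JUDGMENTS_FILE}: unknown group '{jset.group}'"
                )
    if (directory / SCORES_FILE).exists():
        bundle.scores, rep = read_scores(directory / SCORES_FILE)
        bundle.validation.extend(rep)
    return bundle


# ---------------------------------------------------------------- writers

def write_config(config: WorkshopConfig, path: Path) -> None:
    data = {k: getattr(config, k)
            for k in WorkshopConfig.__dataclass_fields__}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_criteria(criteria: list[Criterion], path: Path) -> None:
    rows = [{"stream": c.stream, "id": c.id, "label": c.label,
             "role": c.role,
             **{f"level{l.score}": l.description for l in c.rubric}}
            for c in criteria]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_catalogue(catalogue: list[CandidateItem], path: Path) -> None:
    pd.DataFrame([{"stream": c.stream, "id": c.id, "label": c.label,
                   "source": c.source} for c in catalogue]
                 ).to_csv(path, index=False)


def write_votes(votes: list[VoteRecord], catalogue: list[CandidateItem],
                path: Path) -> None:
    stream_of = {c.id: c.stream for c in catalogue}
    pd.DataFrame([{"participant": v.participant,
                   "stream": stream_of.get(v.item, ""),
                   "item": v.item, "include": int(v.include)}
                  for v in votes]).to_csv(path, index=False)


def write_judgments(judgments: list[JudgmentSet], path: Path) -> None:
    rows = []
    for jset in judgments:
        for (ci, cj), v in jset.judgments.items():
            rows.append({"group": jset.group, "stream": jset.stream,
                         "criterion_i": ci, "criterion_j": cj,
                         "value": format_judgment(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scores(scores: list[OrdinalScore], stream_of: dict[str, str],
                 path: Path) -> None:
    pd.DataFrame([{"group": s.group, "stream": stream_of.get(s.item, ""),
                   "item": s.item, "criterion": s.criterion,
                   "value": s.value} for s in scores]
                 ).to_csv(path, index=False)


def write_bundle_inputs(bundle, directory: str | Path) -> Path:
    """Write a bundle's input files (works for simulated bundles too)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_config(bundle.config, directory / CONFIG_FILE)
    write_criteria(bundle.criteria, directory / CRITERIA_FILE)
    write_catalogue(bundle.catalogue, directory / CATALOGUE_FILE)
    if bundle.votes:
        write_votes(bundle.votes, bundle.catalogue, directory / VOTES_FILE)
    if bundle.judgments:
        write_judgments(bundle.judgments, directory / JUDGMENTS_FILE)
    if bundle.scores:
        stream_of = {c.id: c.stream for c in bundle.catalogue}
        write_scores(bundle.scores, stream_of, directory / SCORES_FILE)
    return directory


def shortlist_frame(shortlist: Shortlist) -> pd.DataFrame:
    return pd.DataFrame(
        [{"stream": shortlist.stream, "item": item, "votes": n,
          "tie_at_cutoff": int(shortlist.tie_at_cutoff)}
         for item, n in shortlist.entries]
    )


def weights_frame(weights: dict[tuple[str, str], WeightVector]) -> pd.DataFrame:
    rows = []
    for (group, stream), wv in sorted(weights.items()):
        for crit, w in zip(wv.criteria, wv.weights):
            rows.append({"group": group, "stream": stream, "criterion": crit,
                         "weight": w, "lambda_max": wv.lambda_max,
                         "CI": wv.consistency_index,
                         "CR": wv.consistency_ratio,
                         "flag": int(wv.inconsistent)})
    return pd.DataFrame(rows)


def composites_frame(composites: dict[str, list[CompositeScore]]
                     ) -> pd.DataFrame:
    rows = [{"group": c.group, "stream": c.stream, "item": c.item,
             "weighted_sum": c.weighted_sum, "multiplier": c.multiplier,
             "composite_value": c.value}
            for stream in sorted(composites) for c in composites[stream]]
    return pd.DataFrame(rows)


def ranking_frame(table: RankingTable) -> pd.DataFrame:
    """Wide per-stream ranking table, one row per item."""
    tie_group = {}
    for i, ts in enumerate(table.combined_ties, start=1):
        for item in ts:
            tie_group[item] = f"T{i}"
    rows = []
    order = sorted(table.combined_rank, key=lambda x: (table.combined_rank[x], x))
    for item in order:
        row: dict = {"stream": table.stream, "item": item}
        for g in table.groups:
            row[f"{g}_composite"] = table.composites[g][item]
            row[f"{g}_normalised"] = table.normalised[g][item]
            row[f"{g}_rank"] = table.group_ranks[g][item]
            row[f"{g}_degenerate"] = int(table.degenerate[g])
        row["combined_score"] = table.combined_score[item]
        row["combined_rank"] = table.combined_rank[item]
        row["tie_group"] = tie_group.get(item, "")
        row["override_note"] = table.overrides_audit.get(item, "")
        rows.append(row)
    return pd.DataFrame(rows)


def export_spreadsheet(bundle: WorkshopBundle, path: str | Path) -> None:
    """One-way spreadsheet export of the computed tables (never an input)."""
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for stream, sl in sorted(bundle.shortlists.items()):
            shortlist_frame(sl).to_excel(xl, sheet_name=f"shortlist_{stream}", index=False)
        if bundle.weights:
            weights_frame(bundle.weights).to_excel(xl, sheet_name="weights", index=False)
        if bundle.composites:
            composites_frame(bundle.composites).to_excel(
                xl, sheet_name="composites", index=False)
        for stream, table in sorted(bundle.rankings.items()):
            ranking_frame(table).to_excel(
                xl, sheet_name=f"ranking_{stream}", index=False)


# ---------------------------------------------------------------- pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_stage(bundle: WorkshopBundle, stage: str, inputs: list[str]) -> None:
    bundle.run_log.append({
        "stage": stage,
        "inputs": {name: _sha256(bundle.directory / name)
                   for name in inputs
                   if (bundle.directory / name).exists()},
        "version": __version__,
    })


def run_pipeline(bundle: WorkshopBundle, upto: str = "ranking",
                 streams: tuple[str, ...] = STREAMS,
                 weight_method: str = "eigenvector",
                 strict_consistency: bool = False,
                 write: bool = True) -> WorkshopBundle:
    """Execute pipeline stages in DAG order through ``upto``.

    Stages: shortlist → weights / scores → composites → ranking. Raises
    if a requested stage's inputs are absent, or (in strict mode) when a
    group's judgments exceed the CR threshold. Deterministic: the same
    input bundle always produces byte-identical output files.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage '{upto}' (expected one of {STAGES})")
    if bundle.validation.errors:
        raise ValueError(
            "bundle has validation errors; fix them first:\n  "
            + "\n  ".join(bundle.validation.errors)
        )
    want = STAGES[: STAGES.index(upto) + 1]
    directory = bundle.directory

    if "shortlist" in want:
        if bundle.votes is None:
            raise ValueError("stage input missing: votes")
        k = {"risk": bundle.config.shortlist_size_risk,
             "disease": bundle.config.shortlist_size_disease}
        for stream in streams:
            cat = [c for c in bundle.catalogue if c.stream == stream]
            ids = {c.id for c in cat}
            counts = tally_votes([v for v in bundle.votes if v.item in ids],
                                 cat)
            sl = select_top(counts, k[stream], stream)
            bundle.shortlists[stream] = sl
            bundle.validation.warnings.extend(sl.warnings)
            if write:
                shortlist_frame(sl).to_csv(
                    directory / f"shortlist_{stream}.csv", index=False)
        _log_stage(bundle, "shortlist", [VOTES_FILE, CATALOGUE_FILE])

    if "weights" in want:
        if bundle.judgments is None:
            raise ValueError("stage input missing: judgments")
        for stream in streams:
            order = [c.id for c in weighted_criteria(bundle.criteria, stream)]
            for group in bundle.config.groups:
                jsets = [j for j in bundle.judgments
                         if j.group == group and j.stream == stream]
                if not jsets:
                    raise ValueError(
                        f"stage input missing: judgments for group "
                        f"'{group}', stream '{stream}'"
                    )
                matrix = expand_matrix(jsets[0], order)
                wv = compute_weights(matrix, weight_method)
                if wv.inconsistent:
                    msg = (f"group '{group}' ({stream}): consistency ratio "
                           f"{wv.consistency_ratio:.3f} > {CR_THRESHOLD}")
                    if strict_consistency:
                        raise ValueError(msg)
                    bundle.validation.warnings.append(msg)
                bundle.weights[(group, stream)] = wv
        if write:
            weights_frame(bundle.weights).to_csv(
                directory / "weights.csv", index=False,
                float_format=FLOAT_FORMAT)
        _log_stage(bundle, "weights", [JUDGMENTS_FILE, CRITERIA_FILE])

    if "scores" in want:
        if bundle.scores is None:
            raise ValueError("stage input missing: scores")
        for stream in streams:
            stream_items = {c.id for c in bundle.catalogue
                            if c.stream == stream}
            sheet = [s for s in bundle.scores if s.item in stream_items]
            rep = validate_scores(sheet, bundle.shortlists[stream],
                                  bundle.criteria, bundle.config.groups,
                                  stream)
            if rep.errors:
                raise ValueError(
                    f"score sheet invalid for stream '{stream}':\n  "
                    + "\n  ".join(rep.errors[:20])
                )
        _log_stage(bundle, "scores", [SCORES_FILE])

    if "composites" in want:
        for stream in streams:
            stream_items = {c.id for c in bundle.catalogue
                            if c.stream == stream}
            sheet = [s for s in bundle.scores if s.item in stream_items]
            weights_by_group = {g: bundle.weights[(g, stream)]
                                for g in bundle.config.groups}
            bundle.composites[stream] = compute_composites(
                sheet, bundle.shortlists[stream], bundle.criteria,
                weights_by_group, stream)
        if write:
            composites_frame(bundle.composites).to_csv(
                directory / "composites.csv", index=False,
                float_format=FLOAT_FORMAT)
        _log_stage(bundle, "composites", [SCORES_FILE, JUDGMENTS_FILE])

    if "ranking" in want:
        for stream in streams:
            per_group: dict[str, dict[str, float]] = {}
            for c in bundle.composites[stream]:
                per_group.setdefault(c.group, {})[c.item] = c.value
            table = build_ranking_table(
                per_group, stream, bundle.config.combined_rank_method)
            bundle.rankings[stream] = table
            if write:
                ranking_frame(table).to_csv(
                    directory / f"ranking_{stream}.csv", index=False,
                    float_format=FLOAT_FORMAT)
        _log_stage(bundle, "ranking", [SCORES_FILE, JUDGMENTS_FILE])

    if write:
        with open(directory / RUN_LOG_FILE, "w", encoding="utf-8") as fh:
            json.dump(bundle.run_log, fh, indent=2)
            fh.write("\n")
    return bundle


# ---------------------------------------------------------------- report

def _text_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "(empty)"
    cells = [[str(c) for c in df.columns]]
    for _, row in df.iterrows():
        cells.append([f"{v:.4f}" if isinstance(v, float) else str(v)
                      for v in row])
    widths = [max(len(r[i]) for r in cells) for i in range(len(cells[0]))]
    lines = ["  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
             for row in cells]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines)


def render_report(bundle: WorkshopBundle, top_n: int = 5
                  ) -> tuple[str, str]:
    """Human-readable summary: top-ranked items, group weights with CR
    flags, ties needing consensus and degenerate-group warnings.

    Returns (plain_text, html). Requires the ranking stage.
    """
    if not bundle.rankings:
        raise ValueError("report requires a completed ranking stage")
    label_of = {c.id: c.label for c in bundle.catalogue}
    sections_txt: list[str] = ["Workshop prioritisation summary",
                               "=" * 31, ""]
    sections_html: list[str] = ["<html><body>",
                                "<h1>Workshop prioritisation summary</h1>"]

    for stream in sorted(bundle.rankings):
        table = bundle.rankings[stream]
        head = f"{stream.capitalize()} stream"
        sections_txt += [head, "-" * len(head)]
        sections_html.append(f"<h2>{head}</h2>")

        order = sorted(table.combined_rank,
                       key=lambda x: (table.combined_rank[x], x))[:top_n]
        top = pd.DataFrame(
            [{"rank": table.combined_rank[i], "item": i,
              "label": label_of.get(i, ""),
              "combined_score": table.combined_score[i]} for i in order]
        )
        sections_txt += [f"Top {top_n} by combined rank "
                         f"({table.combined_method}):",
                         _text_table(top), ""]
        sections_html.append(top.to_html(index=False))

        flags = [f"group '{g}' ({s}): CR = {wv.consistency_ratio:.3f}"
                 for (g, s), wv in sorted(bundle.weights.items())
                 if s == stream and wv.inconsistent]
        sections_txt.append("Consistency flags (CR > 0.1): "
                            + ("; ".join(flags) if flags else "none"))

        ties = ["{" + ", ".join(sorted(ts)) + "}"
                for ts in table.combined_ties]
        sections_txt.append(
            "Ties requiring consensus: " + ("; ".join(ties) if ties else "none"))

        degen = [g for g in table.groups if table.degenerate[g]]
        sections_txt.append(
            "Degenerate groups (all composites equal): "
            + (", ".join(degen) if degen else "none"))
        sections_txt.append("")
        sections_html.append(
            "<p>Consistency flags: " + ("; ".join(flags) or "none")
            + "<br>Ties requiring consensus: " + ("; ".join(ties) or "none")
            + "<br>Degenerate groups: " + (", ".join(degen) or "none")
            + "</p>")

    if bundle.weights:
        wf = weights_frame(bundle.weights)
        sections_txt += ["Group criterion weights", "-" * 23,
                         _text_table(wf), ""]
        sections_html.append("<h2>Group criterion weights</h2>"
                             + wf.to_html(index=False))
    sections_html.append("</body></html>")
    return "\n".join(sections_txt), "\n".join(sections_html)
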