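"""Readers and writers for trial tables.

Two on-disk formats:

* **JSON** — one document holding every subject, experiment and trial,
  plus record-level exchange aggregates. Canonical form (sorted keys,
  2-space indent, trailing newline) so write → read → write is
  byte-identical.
* **CSV** — UTF-8, comma-separated, header row; one file per design.
  Forced columns: ``subject, species, experiment, trial, selected,
  arrived, offered, note``. Free columns: ``subject, species, experiment,
  trial, entered, removed, first_touch, offered, foreign_offer, note``
  with ``removed`` a semicolon-joined label list. Record-level aggregates
  travel in ``#meta`` comment lines, e.g.::

      #meta subject=Manda experiment=exp2 correct_exchanges=6 incorrect_exchanges=0
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    DEFAULT_UNIVERSE,
    ForcedSelectionTrial,
    FreeSelectionTrial,
    ItemUniverse,
    ModelError,
    SubjectRecord,
)

__all__ = ["ValidationError", "load_records", "write_records",
           "FORCED_COLUMNS", "FREE_COLUMNS"]

FORCED_COLUMNS = ["subject", "species", "experiment", "trial",
                  "selected", "arrived", "offered", "note"]
FREE_COLUMNS = ["subject", "species", "experiment", "trial",
                "entered", "removed", "first_touch", "offered",
                "foreign_offer", "note"]

# Experiments whose trials are free-selection sessions.
FREE_EXPERIMENTS = frozenset({"exp2"})


class ValidationError(ModelError):
    """Malformed table contents; the message names the offending row/field."""


def _is_free_experiment(experiment: str) -> bool:
    return experiment in FREE_EXPERIMENTS


# --------------------------------------------------------------------- JSON

def _forced_to_dict(t: ForcedSelectionTrial) -> dict:
    return {"index": t.index, "selected": t.selected,
            "arrived": t.arrived, "offered": t.offered, "note": t.note}


def _free_to_dict(t: FreeSelectionTrial) -> dict:
    return {"index": t.index, "entered": t.entered,
            "removed": sorted(t.removed), "first_touch": t.first_touch,
            "offered": t.offered, "foreign_offer": t.foreign_offer,
            "note": t.note}


def _record_to_dict(rec: SubjectRecord) -> dict:
    experiments = {}
    for exp, trials in rec.experiments.items():
        free = _is_free_experiment(exp)
        experiments[exp] = {
            "design": "free" if free else "forced",
            "trials": [(_free_to_dict if free else _forced_to_dict)(t)
                       for t in trials],
        }
    return {"name": rec.name, "species": rec.species,
            "experiments": experiments, "aggregates": rec.aggregates}


def records_to_json(records: Sequence[SubjectRecord]) -> str:
    doc = {"records": [_record_to_dict(r) for r in records]}
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _trial_from_dict(d: dict, design: str, where: str):
    try:
        if design == "free":
            return FreeSelectionTrial(
                index=int(d["index"]), entered=bool(d["entered"]),
                removed=frozenset(d.get("removed", [])),
                first_touch=d.get("first_touch", "NONE"),
                offered=d.get("offered", "NONE"),
                foreign_offer=d.get("foreign_offer", ""),
                note=d.get("note", ""))
        return ForcedSelectionTrial(
            index=int(d["index"]), selected=d["selected"],
            arrived=bool(d["arrived"]), offered=d.get("offered", "NONE"),
            note=d.get("note", ""))
    except KeyError as exc:
        raise ValidationError(f"{where}: missing field {exc}") from exc


def records_from_json(text: str,
                      universe: ItemUniverse = DEFAULT_UNIVERSE,
                      ) -> list[SubjectRecord]:
    doc = json.loads(text)
    records = []
    for rd in doc.get("records", []):
        experiments = {}
        for exp, block in rd.get("experiments", {}).items():
            design = block.get("design",
                               "free" if _is_free_experiment(exp) else "forced")
            experiments[exp] = [
                _trial_from_dict(td, design, f"{rd.get('name')}/{exp}")
                for td in block["trials"]]
        rec = SubjectRecord(name=rd["name"], species=rd["species"],
                            experiments=experiments,
                            aggregates=rd.get("aggregates", {}))
        _validate_record(rec, universe)
        records.append(rec)
    return records


# ---------------------------------------------------------------------- CSV

def _forced_row(rec: SubjectRecord, exp: str, t: ForcedSelectionTrial) -> list:
    return [rec.name, rec.species, exp, t.index, t.selected,
            int(t.arrived), t.offered, t.note]


def _free_row(rec: SubjectRecord, exp: str, t: FreeSelectionTrial) -> list:
    return [rec.name, rec.species, exp, t.index, int(t.entered),
            ";".join(sorted(t.removed)), t.first_touch, t.offered,
            t.foreign_offer, t.note]


def records_to_csv(records: Sequence[SubjectRecord], design: str) -> str:
    """Render all experiments of one design across records as CSV text."""
    if design not in ("forced", "free"):
        raise ValueError(f"unknown design {design!r}")
    buf = _io.StringIO()
    meta_lines = []
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(FORCED_COLUMNS if design == "forced" else FREE_COLUMNS)
    for rec in records:
        for exp, trials in rec.experiments.items():
            if _is_free_experiment(exp) != (design == "free"):
                continue
            for t in trials:
                writer.writerow(_forced_row(rec, exp, t) if design == "forced"
                                else _free_row(rec, exp, t))
            agg = rec.aggregates.get(exp)
            if agg and design == "free":
                pairs = " ".join(f"{k}={v}" for k, v in sorted(agg.items()))
                meta_lines.append(
                    f"#meta subject={rec.name} experiment={exp} {pairs}")
    return "".join(f"{line}\n" for line in meta_lines) + buf.getvalue()


def _parse_int(value: str, row: int, field: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: field {field!r} is not an integer: {value!r}")


def _parse_meta(line: str) -> tuple[str, str, dict[str, int]]:
    tokens = line[len("#meta"):].split()
    fields = dict(tok.split("=", 1) for tok in tokens)
    subject = fields.pop("subject")
    experiment = fields.pop("experiment")
    return subject, experiment, {k: int(v) for k, v in fields.items()}


def records_from_csv(text: str,
                     universe: ItemUniverse = DEFAULT_UNIVERSE,
                     ) -> list[SubjectRecord]:
    meta = []
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#meta"):
            meta.append(_parse_meta(line))
        elif line.startswith("#") or not line.strip():
            continue
        else:
            data_lines.append(line)
    if not data_lines:
        return []
    reader = csv.DictReader(data_lines)
    header = reader.fieldnames or []
    if "selected" in header:
        design = "forced"
    elif "entered" in header:
        design = "free"
    else:
        raise ValidationError(f"unrecognised CSV header: {header}")

    records: dict[str, SubjectRecord] = {}
    for i, row in enumerate(reader, start=2):
        name = row.get("subject") or ""
        if not name:
            raise ValidationError(f"row {i}: missing subject")
        rec = records.setdefault(
            name, SubjectRecord(name=name, species=row.get("species", "")))
        exp = row.get("experiment") or ""
        if not exp:
            raise ValidationError(f"row {i}: missing experiment")
        idx = _parse_int(row["trial"], i, "trial")
        if design == "forced":
            trial = ForcedSelectionTrial(
                index=idx, selected=row["selected"],
                arrived=bool(_parse_int(row["arrived"], i, "arrived")),
                offered=row["offered"] or "NONE", note=row.get("note") or "")
        else:
            removed = frozenset(x for x in (row["removed"] or "").split(";")
                                if x)
            trial = FreeSelectionTrial(
                index=idx, entered=bool(_parse_int(row["entered"], i,
                                                   "entered")),
                removed=removed, first_touch=row["first_touch"] or "NONE",
                offered=row["offered"] or "NONE",
                foreign_offer=row.get("foreign_offer") or "",
                note=row.get("note") or "")
        trials = rec.experiments.setdefault(exp, [])
        if any(t.index == idx for t in trials):
            raise ValidationError(
                f"row {i}: duplicate trial index {idx} for {name}/{exp}")
        trials.append(trial)
    for subject, experiment, agg in meta:
        if subject not in records:
            raise ValidationError(f"#meta line references unknown subject "
                                  f"{subject!r}")
        records[subject].aggregates.setdefault(experiment, {}).update(agg)
    out = []
    for rec in records.values():
        for trials in rec.experiments.values():
            trials.sort(key=lambda t: t.index)
        _validate_record(rec, universe)
        out.append(rec)
    return out


def _validate_record(rec: SubjectRecord, universe: ItemUniverse) -> None:
    try:
        rec.validate(universe)
    except ModelError as exc:
        raise ValidationError(str(exc)) from exc


# ------------------------------------------------------------------- facade

def load_records(path: str | Path, format: str | None = None,
                 universe: ItemUniverse = DEFAULT_UNIVERSE,
                 ) -> list[SubjectRecord]:
    """Load subject records from a JSON or CSV trial table.

    ``format`` defaults to the file suffix. Raises :class:`ValidationError`
    on malformed rows, duplicate trial indices, unknown item labels, or
    violated invariants.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        return records_from_json(text, universe)
    if fmt == "csv":
        return records_from_csv(text, universe)
    raise ValueError(f"unknown format {fmt!r}")


def write_records(records: Iterable[SubjectRecord], path: str | Path,
                  format: str | None = None, design: str = "forced") -> None:
    """Write records to disk. JSON keeps every experiment; CSV holds one
    design per file (``design`` selects which)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records = list(records)
    if fmt == "json":
        path.write_text(records_to_json(records), encoding="utf-8")
    elif fmt == "csv":
        path.write_text(records_to_csv(records, design), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
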