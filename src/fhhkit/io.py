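"""Readers and writers for every external format the pipeline touches.

Formats: the delimited FHH table (CSV by default, TSV via ``delimiter``),
Brat standoff annotation (.ann/.txt with T/R/A lines), line-delimited
JSON annotation records, FHIR-FamilyMemberHistory-style export, patient
metadata tables, and line-delimited eligibility records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import (
    EligibilityResult,
    Entity,
    EntityLabel,
    FHHEntry,
    OnsetKind,
    OnsetValue,
    PatientProfile,
    Relation,
    RelationType,
    RelativeAssertion,
    Sex,
    Side,
    Status,
)

__all__ = [
    "SchemaError",
    "BratParseError",
    "RowError",
    "read_fhh_table",
    "write_fhh_table",
    "read_patients",
    "group_profiles",
    "read_brat_standoff",
    "write_brat_standoff",
    "write_annotations",
    "read_annotations",
    "export_family_history",
    "write_eligibility",
]

REQUIRED_COLUMNS = ["patient_id", "entry_id", "condition_code", "relative_code",
                    "age_of_onset", "comment", "entry_date"]


class SchemaError(ValueError):
    """Input table is missing a required column."""


class BratParseError(ValueError):
    """Malformed Brat standoff line (carries the line number)."""


@dataclass(frozen=True)
class RowError:
    row: int
    column: str
    message: str


def _cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_fhh_table(path: str | Path, delimiter: str = ",",
                   errors: Optional[list[RowError]] = None) -> list[FHHEntry]:
    """Read a delimited FHH table into entries (order preserved).

    Blank cells become None; a row with an unparseable age of onset is
    kept with a null onset and the problem recorded in ``errors`` (and
    logged) rather than aborting the whole file.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    entries: list[FHHEntry] = []
    for i, row in enumerate(df.itertuples(index=False)):
        onset: Optional[int] = None
        raw_onset = _cell(getattr(row, "age_of_onset"))
        if raw_onset is not None:
            try:
                onset = int(float(raw_onset))
                if not 0 <= onset <= 120:
                    raise ValueError("outside [0, 120]")
            except ValueError as exc:
                onset = None
                err = RowError(i, "age_of_onset", f"unparseable value {raw_onset!r}: {exc}")
                if errors is not None:
                    errors.append(err)
                import logging

                logging.getLogger(__name__).warning("row %d: %s", i, err.message)
        entries.append(
            FHHEntry(
                patient_id=_cell(row.patient_id) or "",
                entry_id=_cell(row.entry_id) or f"row{i}",
                condition_code=_cell(row.condition_code),
                relative_code=_cell(row.relative_code),
                onset_age=onset,
                comment=_cell(row.comment) or "",
                entry_date=_cell(row.entry_date),
            )
        )
    return entries


def write_fhh_table(entries: list[FHHEntry], path: str | Path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "entry_id": e.entry_id,
                "condition_code": e.condition_code,
                "relative_code": e.relative_code,
                "age_of_onset": e.onset_age,
                "comment": e.comment,
                "entry_date": e.entry_date,
            }
            for e in entries
        ],
        columns=REQUIRED_COLUMNS,
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_patients(path: str | Path, delimiter: str = ",") -> dict[str, dict]:
    """Patient metadata keyed by patient_id (age, sex, ashkenazi_jewish)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "patient_id" not in df.columns:
        raise SchemaError("missing required column: patient_id")
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        aj = _cell(getattr(row, "ashkenazi_jewish", None))
        age = _cell(getattr(row, "age", None))
        out[str(row.patient_id)] = {
            "age": int(age) if age else None,
            "sex": Sex[_cell(getattr(row, "sex", None)) or "UNKNOWN"],
            "ashkenazi_jewish": None if aj is None else aj.lower() in ("1", "true", "yes"),
        }
    return out


def group_profiles(entries: list[FHHEntry],
                   metadata: Optional[dict[str, dict]] = None) -> list[PatientProfile]:
    """Group entries into per-patient profiles, preserving first-seen order."""
    by_patient: dict[str, list[FHHEntry]] = {}
    for e in entries:
        by_patient.setdefault(e.patient_id, []).append(e)
    profiles = []
    for pid, pentries in by_patient.items():
        meta = (metadata or {}).get(pid, {})
        profiles.append(
            PatientProfile(
                patient_id=pid,
                age=meta.get("age"),
                sex=meta.get("sex", Sex.UNKNOWN),
                ashkenazi_jewish=meta.get("ashkenazi_jewish"),
                entries=pentries,
            )
        )
    return profiles


# --- Brat standoff ------------------------------------------------------

def write_brat_standoff(entities: list[Entity], relations: list[Relation],
                        ann_path: str | Path, text: str,
                        txt_path: Optional[str | Path] = None) -> None:
    """Write entities/relations as Brat standoff (T/R/A lines)."""
    if txt_path is not None:
        Path(txt_path).write_text(text, encoding="utf-8")
    lines: list[str] = []
    tid_of: dict[int, str] = {}
    aid = 0
    for i, e in enumerate(entities, 1):
        tid = f"T{i}"
        tid_of[e.eid] = tid
        lines.append(f"{tid}\t{e.label.value} {e.start} {e.end}\t{text[e.start:e.end]}")
        for name, value in (
            ("STATUS", e.status.value if e.status is not Status.ACTIVE else None),
            ("CODE", e.code),
            ("SIDE", e.side.value if e.side is not Side.UNKNOWN else None),
            ("SEX", e.sex.value if e.sex is not Sex.UNKNOWN else None),
        ):
            if value:
                aid += 1
                lines.append(f"A{aid}\t{name} {tid} {value}")
        if e.is_structural:
            aid += 1
            lines.append(f"A{aid}\tIS_STRUCTURAL {tid}")
        if e.uncertainty:
            aid += 1
            lines.append(f"A{aid}\tUNCERTAINTY {tid}")
    for j, r in enumerate(relations, 1):
        lines.append(
            f"R{j}\t{r.type.value} Arg1:{tid_of[r.source.eid]} Arg2:{tid_of[r.target.eid]}"
        )
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_brat_standoff(ann_path: str | Path,
                       txt_path: str | Path) -> tuple[str, list[Entity], list[Relation]]:
    """Parse Brat standoff into entities and relations.

    T lines become entities, R lines relations, A lines populate features.
    A relation argument referencing an unknown T id raises
    :class:`BratParseError` with the offending line number.
    """
    text = Path(txt_path).read_text(encoding="utf-8")
    entities: dict[str, Entity] = {}
    pending_relations: list[tuple[int, str, str, str]] = []
    for lineno, line in enumerate(Path(ann_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        tag, rest = line.split("\t", 1)
        if tag.startswith("T"):
            header, surface = (rest.split("\t", 1) + [""])[:2]
            label, start, end = header.split()[:3]
            start, end = int(start), int(end)
            if end > len(text):
                raise BratParseError(f"line {lineno}: span {start}:{end} beyond text")
            entities[tag] = Entity(start, end, surface or text[start:end],
                                   EntityLabel[label])
        elif tag.startswith("R"):
            parts = rest.split()
            rtype = parts[0]
            args = dict(p.split(":", 1) for p in parts[1:3])
            pending_relations.append((lineno, rtype, args["Arg1"], args["Arg2"]))
        elif tag.startswith("A"):
            parts = rest.split()
            name, tid = parts[0], parts[1]
            if tid not in entities:
                raise BratParseError(f"line {lineno}: attribute references unknown {tid}")
            ent = entities[tid]
            if name == "STATUS":
                ent.status = Status[parts[2]]
            elif name == "CODE":
                ent.code = parts[2]
            elif name == "SIDE":
                ent.side = Side[parts[2]]
            elif name == "SEX":
                ent.sex = Sex[parts[2]]
            elif name == "IS_STRUCTURAL":
                ent.is_structural = True
            elif name == "UNCERTAINTY":
                ent.uncertainty = True
    relations = []
    for lineno, rtype, a1, a2 in pending_relations:
        if a1 not in entities or a2 not in entities:
            raise BratParseError(f"line {lineno}: dangling relation argument")
        relations.append(Relation(RelationType[rtype], entities[a1], entities[a2]))
    return text, list(entities.values()), relations


# --- line-delimited annotation records ----------------------------------

def _entity_record(e: Entity) -> dict:
    rec = {
        "start": e.start,
        "end": e.end,
        "surface": e.surface,
        "label": e.label.value,
        "is_structural": e.is_structural,
        "uncertainty": e.uncertainty,
        "status": e.status.value,
        "code": e.code,
        "side": e.side.value,
        "sex": e.sex.value,
        "multiplicity": e.multiplicity,
        "eid": e.eid,
    }
    if e.onset is not None:
        rec["onset"] = {"kind": e.onset.kind.value, "lower": e.onset.lower,
                        "upper": e.onset.upper, "raw": e.onset.raw}
    return rec


_ENTITY_FIELDS = {"start": int, "end": int, "surface": str, "label": str,
                  "is_structural": bool, "uncertainty": bool, "status": str,
                  "side": str, "sex": str, "multiplicity": int, "eid": int}


def _validate_entity_record(rec: dict, lineno: int) -> None:
    for name, typ in _ENTITY_FIELDS.items():
        if name not in rec:
            raise ValueError(f"line {lineno}: entity record missing field {name!r}")
        if not isinstance(rec[name], typ):
            raise ValueError(f"line {lineno}: entity field {name!r} has wrong type")


def _entity_from_record(rec: dict) -> Entity:
    onset = None
    if rec.get("onset"):
        o = rec["onset"]
        onset = OnsetValue(OnsetKind[o["kind"]], o["lower"], o["upper"], o.get("raw", ""))
    return Entity(
        start=rec["start"], end=rec["end"], surface=rec["surface"],
        label=EntityLabel[rec["label"]], is_structural=rec["is_structural"],
        uncertainty=rec["uncertainty"], status=Status[rec["status"]],
        code=rec.get("code"), side=Side[rec["side"]], sex=Sex[rec["sex"]],
        multiplicity=rec["multiplicity"], onset=onset, eid=rec["eid"],
    )


def write_annotations(records: list[dict], path: str | Path) -> None:
    """Write per-entry annotation records as JSON lines.

    Each record: ``{"entry_id", "text", "entities": [...], "relations":
    [{"type", "source_eid", "target_eid"}]}``.  Use
    :func:`annotation_record` to build one from pipeline output.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def annotation_record(entry_id: str, text: str, entities: list[Entity],
                      relations: list[Relation]) -> dict:
    return {
        "entry_id": entry_id,
        "text": text,
        "entities": [_entity_record(e) for e in entities],
        "relations": [
            {"type": r.type.value, "source_eid": r.source.eid, "target_eid": r.target.eid}
            for r in relations
        ],
    }


def read_annotations(path: str | Path) -> list[dict]:
    """Read JSON-line annotation records back, rebuilding entity/relation objects."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            rec = json.loads(line)
            for key in ("entry_id", "text", "entities", "relations"):
                if key not in rec:
                    raise ValueError(f"line {lineno}: record missing field {key!r}")
            for e in rec["entities"]:
                _validate_entity_record(e, lineno)
            entities = [_entity_from_record(e) for e in rec["entities"]]
            by_eid = {e.eid: e for e in entities}
            relations = []
            for r in rec["relations"]:
                if r["source_eid"] not in by_eid or r["target_eid"] not in by_eid:
                    raise ValueError(f"line {lineno}: relation references unknown entity")
                relations.append(
                    Relation(RelationType[r["type"]], by_eid[r["source_eid"]],
                             by_eid[r["target_eid"]])
                )
            out.append({"entry_id": rec["entry_id"], "text": rec["text"],
                        "entities": entities, "relations": relations})
    return out


# --- FHIR-style export ---------------------------------------------------

_SITE_DISPLAY = {
    "BREAST": "breast cancer", "OVARIAN": "ovarian cancer", "COLON": "colon cancer",
    "RECTAL": "rectal cancer", "PANCREAS": "pancreatic cancer",
    "PROSTATE": "prostate cancer", "STOMACH": "stomach cancer",
    "KIDNEY": "kidney cancer", "BLADDER": "bladder cancer", "BRAIN": "brain cancer",
    "SMALL_INTESTINE": "small intestine cancer", "URETERAL": "ureteral cancer",
    "URETHRAL": "urethral cancer", "ENDOMETRIAL": "endometrial cancer",
    "CANCER": "cancer",
}


def export_family_history(assertions: list[RelativeAssertion],
                          patient: PatientProfile, path: str | Path) -> None:
    """Write assertions as a FamilyMemberHistory-style JSON bundle.

    One record per asserted individual: an assertion with count N emits N
    records.  Uncertainty is carried as a boolean extension rather than
    dropped, so both uncertainty policies stay computable downstream.
    """
    resources = []
    for a in assertions:
        condition: dict = {
            "code": {"text": _SITE_DISPLAY.get(a.condition, a.condition)},
        }
        if a.onset is not None:
            if a.onset.kind is OnsetKind.AGE:
                condition["onsetAge"] = {"value": a.onset.lower, "unit": "years"}
            elif a.onset.kind is OnsetKind.RANGE:
                condition["onsetRange"] = {
                    "low": {"value": a.onset.lower, "unit": "years"},
                    "high": {"value": a.onset.upper, "unit": "years"},
                }
            else:
                condition["onsetString"] = a.onset.raw
        resource = {
            "resourceType": "FamilyMemberHistory",
            "status": "completed",
            "patient": {"reference": f"Patient/{patient.patient_id}"},
            "relationship": {"text": a.relative_code.replace("_", " ").lower()},
            "condition": [condition],
            "extension": [
                {"url": "uncertainty", "valueBoolean": a.uncertain},
            ],
        }
        if a.side is not Side.UNKNOWN:
            resource["extension"].append({"url": "familySide", "valueString": a.side.value})
        resources.extend([resource] * a.count)
    bundle = {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }
    Path(path).write_text(json.dumps(bundle, indent=2) + "\n", encoding="utf-8")


def write_eligibility(results: list[EligibilityResult], path: str | Path) -> None:
    """Line-delimited eligibility records (one per patient per cohort)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps({
                "patient_id": r.patient_id,
                "cohort": r.cohort.value,
                "eligible": r.eligible,
                "criteria": list(r.matched_criteria),
                "mode": r.mode.value,
                "uncertainty_policy": r.uncertainty_policy.value,
            }) + "\n")
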