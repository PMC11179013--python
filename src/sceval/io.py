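"""Readers and writers for study files.

Canonical on-disk format is a single JSON document.  A "csv-bundle"
(a directory holding ``vignettes.json``, ``lexicon.json``,
``consultations.csv`` and optionally ``metadata.json``) is accepted for
spreadsheet-driven studies.  ``save_study`` followed by ``load_study``
is the identity on a valid :class:`~sceval.types.StudyDataset`.

ABSENT outcomes are encoded as ``null`` in JSON and as the empty string
in CSV; they are never conflated with a real condition code.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

from .types import (
    ABSENT,
    AnsweredSymptom,
    ConceptLexicon,
    ConsultationRecord,
    StudyDataset,
    TriageLevel,
    ValidationError,
    Vignette,
    _AbsentType,
)

SCHEMA_VERSION = 1

_CSV_COLUMNS = [
    "vignette_id",
    "tester_id",
    "round",
    "regime",
    "entered_complaints",
    "answered_symptoms",
    "entered_duration",
    "entered_age",
    "entered_sex",
    "entered_comorbidities",
    "outcome_condition",
    "outcome_condition_list",
    "outcome_triage",
]


def _triage_out(t: Union[TriageLevel, _AbsentType]) -> Optional[str]:
    return None if t is ABSENT else t.label


def _vignette_to_json(v: Vignette) -> dict:
    return {
        "id": v.id,
        "age": v.age,
        "sex": v.sex,
        "duration": v.duration,
        "symptoms": sorted(v.symptoms),
        "comorbidities": sorted(v.comorbidities),
        "prescribed_complaints": v.prescribed_complaints,
        "gold_condition": v.gold_condition,
        "gold_triage": v.gold_triage.label,
    }


def _vignette_from_json(d: dict) -> Vignette:
    try:
        return Vignette(
            id=d["id"],
            age=d["age"],
            sex=d["sex"],
            duration=d["duration"],
            symptoms=set(d["symptoms"]),
            comorbidities=set(d.get("comorbidities", [])),
            prescribed_complaints=d.get("prescribed_complaints"),
            gold_condition=d["gold_condition"],
            gold_triage=TriageLevel.from_label(d["gold_triage"]),
        )
    except KeyError as e:
        raise ValidationError(f"vignette record missing field {e.args[0]!r}: {d!r}") from None


def _consultation_to_json(c: ConsultationRecord) -> dict:
    return {
        "vignette_id": c.vignette_id,
        "tester_id": c.tester_id,
        "round": c.round,
        "regime": c.regime,
        "entered_complaints": list(c.entered_complaints),
        "answered_symptoms": [
            {"concept": a.concept, "answer": a.answer, "forced": a.forced}
            for a in c.answered_symptoms
        ],
        "entered_duration": c.entered_duration,
        "entered_age": c.entered_age,
        "entered_sex": c.entered_sex,
        "entered_comorbidities": sorted(c.entered_comorbidities),
        "outcome_condition": None if c.outcome_condition is ABSENT else c.outcome_condition,
        "outcome_condition_list": list(c.outcome_condition_list),
        "outcome_triage": _triage_out(c.outcome_triage),
    }


def _consultation_from_json(d: dict) -> ConsultationRecord:
    try:
        cond = d["outcome_condition"]
        triage = d["outcome_triage"]
        return ConsultationRecord(
            vignette_id=d["vignette_id"],
            tester_id=d["tester_id"],
            round=d["round"],
            regime=d["regime"],
            entered_complaints=list(d["entered_complaints"]),
            answered_symptoms=[
                AnsweredSymptom(a["concept"], a["answer"], bool(a.get("forced", False)))
                for a in d.get("answered_symptoms", [])
            ],
            entered_duration=d["entered_duration"],
            entered_age=d["entered_age"],
            entered_sex=d["entered_sex"],
            entered_comorbidities=set(d.get("entered_comorbidities", [])),
            outcome_condition=ABSENT if cond is None else cond,
            outcome_condition_list=list(d.get("outcome_condition_list", [])),
            outcome_triage=ABSENT if triage is None else TriageLevel.from_label(triage),
        )
    except KeyError as e:
        raise ValidationError(f"consultation record missing field {e.args[0]!r}") from None


def _lexicon_to_json(lex: ConceptLexicon) -> dict:
    return {
        c: {
            "synonyms": sorted(lex.synonyms.get(c, set())),
            "parent": lex.parent.get(c),
        }
        for c in sorted(lex.concepts)
    }


def _lexicon_from_json(d: dict) -> ConceptLexicon:
    concepts = set(d)
    synonyms = {c: set(entry.get("synonyms", [])) for c, entry in d.items() if entry.get("synonyms")}
    parent = {c: entry["parent"] for c, entry in d.items() if entry.get("parent")}
    return ConceptLexicon(concepts=concepts, synonyms=synonyms, parent=parent)


def study_to_json(ds: StudyDataset) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": ds.metadata,
        "lexicon": _lexicon_to_json(ds.lexicon),
        "vignettes": [_vignette_to_json(v) for v in ds.vignettes.values()],
        "consultations": [_consultation_to_json(c) for c in ds.consultations],
    }


def study_from_json(doc: dict) -> StudyDataset:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"unrecognized schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    vignettes = {}
    for vd in doc.get("vignettes", []):
        v = _vignette_from_json(vd)
        if v.id in vignettes:
            raise ValidationError(f"duplicate vignette id {v.id!r}")
        vignettes[v.id] = v
    consultations = [_consultation_from_json(cd) for cd in doc.get("consultations", [])]
    lexicon = _lexicon_from_json(doc.get("lexicon", {}))
    return StudyDataset(
        vignettes=vignettes,
        consultations=consultations,
        lexicon=lexicon,
        metadata=doc.get("metadata", {}),
    )


def _join(items, sep: str) -> str:
    return sep.join(str(x) for x in items)


def _consultation_to_row(c: ConsultationRecord) -> dict:
    answers = ";".join(
        f"{a.concept}:{a.answer}" + ("!" if a.forced else "")
        for a in c.answered_symptoms
    )
    return {
        "vignette_id": c.vignette_id,
        "tester_id": c.tester_id,
        "round": c.round,
        "regime": c.regime,
        "entered_complaints": _join(c.entered_complaints, "|"),
        "answered_symptoms": answers,
        "entered_duration": c.entered_duration,
        "entered_age": c.entered_age,
        "entered_sex": c.entered_sex,
        "entered_comorbidities": _join(sorted(c.entered_comorbidities), "|"),
        "outcome_condition": "" if c.outcome_condition is ABSENT else c.outcome_condition,
        "outcome_condition_list": _join(c.outcome_condition_list, "|"),
        "outcome_triage": "" if c.outcome_triage is ABSENT else c.outcome_triage.label,
    }


def _maybe_int(s: str) -> Union[int, str]:
    try:
        return int(s)
    except ValueError:
        return s


def _consultation_from_row(row: dict) -> ConsultationRecord:
    answers = []
    for part in filter(None, row["answered_symptoms"].split(";")):
        forced = part.endswith("!")
        if forced:
            part = part[:-1]
        concept, _, answer = part.rpartition(":")
        answers.append(AnsweredSymptom(concept, answer, forced))
    cond = row["outcome_condition"]
    triage = row["outcome_triage"]
    return ConsultationRecord(
        vignette_id=row["vignette_id"],
        tester_id=row["tester_id"],
        round=int(row["round"]),
        regime=row["regime"],
        entered_complaints=[s for s in row["entered_complaints"].split("|") if s],
        answered_symptoms=answers,
        entered_duration=_maybe_int(row["entered_duration"]),
        entered_age=int(row["entered_age"]),
        entered_sex=row["entered_sex"],
        entered_comorbidities={s for s in row["entered_comorbidities"].split("|") if s},
        outcome_condition=ABSENT if cond == "" else cond,
        outcome_condition_list=[s for s in row.get("outcome_condition_list", "").split("|") if s],
        outcome_triage=ABSENT if triage == "" else TriageLevel.from_label(triage),
    )


def save_study(ds: StudyDataset, path, format: str = "json") -> Path:
    """Write *ds* to *path*; returns the path written.

    ``format="json"`` writes one JSON document; ``format="csv-bundle"``
    writes a directory of per-table files.
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(study_to_json(ds), indent=1), encoding="utf-8")
        return path
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        (path / "vignettes.json").write_text(
            json.dumps([_vignette_to_json(v) for v in ds.vignettes.values()], indent=1),
            encoding="utf-8",
        )
        (path / "lexicon.json").write_text(
            json.dumps(_lexicon_to_json(ds.lexicon), indent=1), encoding="utf-8"
        )
        (path / "metadata.json").write_text(
            json.dumps(ds.metadata, indent=1), encoding="utf-8"
        )
        with (path / "consultations.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for c in ds.consultations:
                writer.writerow(_consultation_to_row(c))
        return path
    raise ValueError(f"unknown format {format!r}; use 'json' or 'csv-bundle'")


def load_study(path, format: Optional[str] = None) -> StudyDataset:
    """Load and validate a study from *path*.

    *format* is auto-detected (directory -> csv-bundle, file -> json)
    unless given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise ValidationError(f"{path}: not valid JSON: {e}") from None
        return study_from_json(doc)
    if format == "csv-bundle":
        vigs = json.loads((path / "vignettes.json").read_text(encoding="utf-8"))
        lex = json.loads((path / "lexicon.json").read_text(encoding="utf-8"))
        meta_path = path / "metadata.json"
        metadata = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
        consultations = []
        with (path / "consultations.csv").open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                consultations.append(_consultation_from_row(row))
        vignettes = {}
        for vd in vigs:
            v = _vignette_from_json(vd)
            if v.id in vignettes:
                raise ValidationError(f"duplicate vignette id {v.id!r}")
            vignettes[v.id] = v
        return StudyDataset(
            vignettes=vignettes,
            consultations=consultations,
            lexicon=_lexicon_from_json(lex),
            metadata=metadata,
        )
    raise ValueError(f"unknown format {format!r}; use 'json' or 'csv-bundle'")
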