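"""Reading and writing note corpora and screening output.

Corpora travel as JSONL — one JSON object per line with ``note_id`` (or
``id``), ``text`` and optional ``sections``, ``icd_codes``, ``label`` — or as
a directory of plain-text files (one note per ``*.txt``, file stem as id).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from .textprep import Note, ScreenResult

__all__ = ["read_notes_jsonl", "write_notes_jsonl", "read_notes_dir", "write_screening_csv"]


def _note_from_record(rec: dict) -> Note:
    note_id = rec.get("note_id", rec.get("id"))
    if note_id is None:
        raise ValueError(f"record missing 'note_id': {rec!r}")
    return Note(
        note_id=str(note_id),
        text=rec["text"],
        sections=rec.get("sections"),
        icd_codes=rec.get("icd_codes"),
        label=rec.get("label"),
    )


def read_notes_jsonl(path) -> list[Note]:
    notes = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            note = _note_from_record(json.loads(line))
            if note.note_id in seen:
                raise ValueError(f"duplicate note_id {note.note_id!r} at line {i + 1}")
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_notes_jsonl(notes: Iterable[Note], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            rec = {"note_id": n.note_id, "text": n.text}
            if n.sections is not None:
                rec["sections"] = n.sections
            if n.icd_codes is not None:
                rec["icd_codes"] = n.icd_codes
            if n.label is not None:
                rec["label"] = n.label
            fh.write(json.dumps(rec) + "\n")


def read_notes_dir(path) -> list[Note]:
    """Read every ``*.txt`` file under ``path`` as one note (file stem as id)."""
    notes = []
    for p in sorted(Path(path).glob("*.txt")):
        notes.append(Note(note_id=p.stem, text=p.read_text(encoding="utf-8")))
    return notes


def write_screening_csv(results: Sequence[tuple[str, ScreenResult]], path) -> None:
    """Write screening verdicts as CSV rows (note_id, flag, evidence)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["note_id", "flag", "evidence"])
        for note_id, res in results:
            ev = "; ".join(f"{p}@{a}:{b}" for p, (a, b) in res.evidence)
            w.writerow([note_id, res.flag, ev])
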