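"""Readers and writers: JSONL notes/annotations, CoNLL-style BIO corpora,
correction lists, and evaluation reports.

Notes travel as JSONL, one object per line with keys ``note_id``,
``department``, ``text`` and (optionally) gold spans under ``phi``.  A
leading ``{"_meta": ...}`` line carrying the seeds/config hash that
produced an artifact is tolerated and skipped by every reader.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Optional, Sequence, Tuple

from .core import AnnotatedNote, ClinicalNote, PHIAnnotation, PHICategory, PersonRole, Span
from .errors import NoteFormatError
from .pseudo_label import (
    CorrectionList,
    LabeledToken,
    TaggedCorpus,
    TaggedNote,
    Tier,
    is_bio_valid,
)
from .tokenize import tokenize


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, ensure_ascii=False, default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def _meta_line(meta: Optional[dict]) -> List[str]:
    if not meta:
        return []
    return [json.dumps({"_meta": meta}, sort_keys=True, ensure_ascii=False)]


# ---------------------------------------------------------------------------
# JSONL notes
# ---------------------------------------------------------------------------

def _note_from_record(rec: dict, lineno: int) -> AnnotatedNote:
    try:
        note = ClinicalNote(
            note_id=str(rec["note_id"]),
            department=rec.get("department", "radiology"),
            text=rec["text"],
        )
    except KeyError as exc:
        raise NoteFormatError(f"line {lineno}: missing key {exc}") from exc
    anns: List[PHIAnnotation] = []
    for a in rec.get("phi") or []:
        cat = PHICategory(a["category"])
        sub = PersonRole(a["subcategory"]) if a.get("subcategory") else None
        span = Span(int(a["start"]), int(a["end"]))
        anns.append(PHIAnnotation(span=span, category=cat, surface=span.slice(note.text), subcategory=sub))
    return AnnotatedNote(note, anns)


def read_notes(path: str) -> List[AnnotatedNote]:
    """Read notes (with optional gold annotations) from JSONL."""
    out: List[AnnotatedNote] = []
    seen = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise NoteFormatError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            if "_meta" in rec:
                continue
            annotated = _note_from_record(rec, lineno)
            if annotated.note.note_id in seen:
                raise NoteFormatError(f"{path}: line {lineno}: duplicate note_id {annotated.note.note_id!r}")
            seen.add(annotated.note.note_id)
            out.append(annotated)
    return out


def write_notes(path: str, notes: Sequence[AnnotatedNote], meta: Optional[dict] = None) -> None:
    lines = _meta_line(meta)
    for an in notes:
        rec = {
            "note_id": an.note.note_id,
            "department": an.note.department.value,
            "text": an.note.text,
        }
        if an.annotations:
            rec["phi"] = [
                {
                    "start": a.span.start,
                    "end": a.span.end,
                    "category": a.category.value,
                    "subcategory": a.subcategory.value if a.subcategory else None,
                }
                for a in an.annotations
            ]
        lines.append(json.dumps(rec, sort_keys=True, ensure_ascii=False))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# CoNLL-style two-column BIO corpora
# ---------------------------------------------------------------------------

def write_conll(corpus: TaggedCorpus, path: str, meta: Optional[dict] = None) -> None:
    """token TAB tag lines, blank line between notes; ``# note_id`` comment
    lines preserve identity for evaluation round trips."""
    lines: List[str] = []
    if meta:
        lines.append("# meta " + json.dumps(meta, sort_keys=True, ensure_ascii=False))
    lines.append(f"# tier {corpus.tier.value}")
    for tn in corpus.notes:
        if not is_bio_valid([t.tag for t in tn.tokens]):
            raise NoteFormatError(f"note {tn.note.note_id!r} has an invalid BIO sequence")
        lines.append(f"# note_id {tn.note.note_id}")
        for tok in tn.tokens:
            lines.append(f"{tok.surface}\t{tok.tag}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_conll(path: str) -> TaggedCorpus:
    """Inverse of write_conll on tokens and tags.

    Character spans are not stored in CoNLL; they are rebuilt by placing
    tokens one space apart, which keeps both sides of an evaluation aligned
    as long as the token sequences agree.
    """
    notes: List[TaggedNote] = []
    tier = Tier.CUSTOM
    cur_tokens: List[Tuple[str, str]] = []
    cur_id: Optional[str] = None
    counter = 0

    def flush() -> None:
        nonlocal cur_tokens, cur_id, counter
        if not cur_tokens:
            cur_id = None
            return
        pos = 0
        toks: List[LabeledToken] = []
        for surface, tag in cur_tokens:
            toks.append(LabeledToken(surface, Span(pos, pos + len(surface)), tag))
            pos += len(surface) + 1
        text = " ".join(s for s, _ in cur_tokens)
        note_id = cur_id if cur_id is not None else f"conll-{counter:06d}"
        counter += 1
        notes.append(TaggedNote(ClinicalNote(note_id, "radiology", text), toks))
        cur_tokens = []
        cur_id = None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("# tier "):
                tier = Tier(line[len("# tier "):].strip())
            elif line.startswith("# note_id "):
                cur_id = line[len("# note_id "):].strip()
            elif line.startswith("#"):
                continue
            elif not line.strip():
                flush()
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise NoteFormatError(f"{path}: line {lineno}: expected 'token<TAB>tag'")
                cur_tokens.append((parts[0], parts[1]))
    flush()
    from .pseudo_label import count_phi_words

    return TaggedCorpus(tier=tier, notes=notes, phi_word_counts=count_phi_words(notes))


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------

def read_corrections(path: str) -> CorrectionList:
    removals: List[Tuple[str, Span]] = []
    additions: List[AnnotatedNote] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "_meta" in rec:
                continue
            kind = rec.get("kind")
            if kind == "removal":
                removals.append((str(rec["note_id"]), Span(int(rec["start"]), int(rec["end"]))))
            elif kind == "addition":
                additions.append(_note_from_record(rec["note"], lineno))
            else:
                raise NoteFormatError(f"{path}: line {lineno}: unknown correction kind {kind!r}")
    return CorrectionList(removals=removals, additions=additions)


def write_corrections(path: str, corrections: CorrectionList, meta: Optional[dict] = None) -> None:
    lines = _meta_line(meta)
    for note_id, span in corrections.removals:
        lines.append(
            json.dumps(
                {"kind": "removal", "note_id": note_id, "start": span.start, "end": span.end},
                sort_keys=True,
                ensure_ascii=False,
            )
        )
    for an in corrections.additions:
        rec = {
            "note_id": an.note.note_id,
            "department": an.note.department.value,
            "text": an.note.text,
            "phi": [
                {
                    "start": a.span.start,
                    "end": a.span.end,
                    "category": a.category.value,
                    "subcategory": a.subcategory.value if a.subcategory else None,
                }
                for a in an.annotations
            ],
        }
        lines.append(json.dumps({"kind": "addition", "note": rec}, sort_keys=True, ensure_ascii=False))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
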