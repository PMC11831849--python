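"""Shared domain types and coordinate conventions.

All character offsets in deidkit are 0-based, half-open, and counted in
Unicode code points of the NFC-normalized note text.  Korean clinical text
mixes precomposed and decomposed Hangul depending on the editor that wrote
it, so every string is NFC-normalized at ingestion; all downstream regex
matching and span arithmetic assume that canonical form.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import NoteFormatError


class PHICategory(str, Enum):
    """The six top-level PHI categories.

    DAT dates, PER person names (staff or patient), ORG hospitals and other
    institutions, LOC standalone region names, NUM phone/extension and
    patient numbers, ETC age / sex / nationality.
    """

    DAT = "DAT"
    PER = "PER"
    ORG = "ORG"
    LOC = "LOC"
    NUM = "NUM"
    ETC = "ETC"


class PersonRole(str, Enum):
    """Sub-category of PER: hospital staff vs. patient."""

    STAFF = "staff"
    PATIENT = "patient"


class Department(str, Enum):
    RADIOLOGY = "radiology"
    OTHER = "other"


def normalize_text(raw, note_id: Optional[str] = None) -> str:
    """NFC-normalize note text.  Idempotent.

    Raises NoteFormatError (naming ``note_id`` when given) if ``raw`` is not
    text or is undecodable bytes.
    """
    if isinstance(raw, bytes):
        try:
            raw = raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            where = f" in note {note_id!r}" if note_id else ""
            raise NoteFormatError(f"undecodable UTF-8 text{where}: {exc}") from exc
    if not isinstance(raw, str):
        where = f" in note {note_id!r}" if note_id else ""
        raise NoteFormatError(f"note text must be a string{where}, got {type(raw).__name__}")
    return unicodedata.normalize("NFC", raw)


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [start, end) in code points."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


@dataclass(frozen=True)
class PHIAnnotation:
    """A character span tagged with a PHI category.

    ``surface`` must equal the slice of the note text at ``span``; PER
    annotations carry a role sub-category, all other categories must not.
    """

    span: Span
    category: PHICategory
    surface: str
    subcategory: Optional[PersonRole] = None

    def __post_init__(self) -> None:
        if self.category is PHICategory.PER and self.subcategory is None:
            raise ValueError("PER annotation requires a staff/patient subcategory")
        if self.category is not PHICategory.PER and self.subcategory is not None:
            raise ValueError(f"subcategory is only valid for PER, not {self.category.value}")

    def check_against(self, text: str) -> None:
        """Verify the surface/span round-trip against the note text."""
        if self.span.end > len(text):
            raise NoteFormatError(
                f"annotation span [{self.span.start}, {self.span.end}) exceeds note length {len(text)}"
            )
        got = self.span.slice(text)
        if got != self.surface:
            raise NoteFormatError(
                f"annotation surface {self.surface!r} != text slice {got!r} at "
                f"[{self.span.start}, {self.span.end})"
            )


@dataclass
class ClinicalNote:
    """One clinical note: opaque id, department flavor, NFC text."""

    note_id: str
    department: Department
    text: str

    def __post_init__(self) -> None:
        if isinstance(self.department, str):
            self.department = Department(self.department)
        self.text = normalize_text(self.text, note_id=self.note_id)
        if not self.text:
            raise NoteFormatError(f"note {self.note_id!r} has empty text after normalization")


# Convenience container used throughout: a note paired with its gold spans.
@dataclass
class AnnotatedNote:
    note: ClinicalNote
    annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            ann.check_against(self.note.text)
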