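"""Pseudo-labeling: project rule matches onto token-level BIO tags and
build tiered training corpora, including the corpus-correction workflow.

Tags use the BIO2 scheme over the six PHI categories (13 tags total);
staff and patient sub-categories both collapse to PER.  A token inherits a
category as soon as one of its characters overlaps a match — masking must
never leak a partial name or date fragment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .core import AnnotatedNote, ClinicalNote, PHIAnnotation, PHICategory, Span
from .errors import CorpusError, CorrectionError, DeidError
from .rules import RuleMatch, RuleSet, apply_rules
from .tokenize import tokenize

BIO_TAGS = ["O"] + [f"{p}-{c.value}" for c in PHICategory for p in ("B", "I")]


class Tier(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE1 = "large1"
    LARGE2 = "large2"
    CUSTOM = "custom"


@dataclass(frozen=True)
class LabeledToken:
    surface: str
    span: Span
    tag: str

    @property
    def category(self) -> Optional[str]:
        """B/I collapsed to the bare category; None for O."""
        return None if self.tag == "O" else self.tag.split("-", 1)[1]


@dataclass
class TaggedNote:
    note: ClinicalNote
    tokens: List[LabeledToken]


@dataclass
class TaggedCorpus:
    tier: Tier
    notes: List[TaggedNote]
    phi_word_counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.notes)


@dataclass
class CorrectionList:
    """Corpus-level corrections: false-positive spans to revert to O, and
    gold-annotated notes (typically from other departments) to append."""

    removals: List[Tuple[str, Span]] = field(default_factory=list)
    additions: List[AnnotatedNote] = field(default_factory=list)


def is_bio_valid(tags: Sequence[str]) -> bool:
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and prev not in (f"B-{tag[2:]}", tag):
            return False
        prev = tag
    return True


def _spans_sorted_disjoint(spans: Sequence[Span]) -> None:
    ordered = sorted(spans, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise DeidError(f"overlapping spans {a} and {b}")


def project_to_bio(
    tokens: Sequence[Tuple[str, Span]],
    matches: Sequence[Union[RuleMatch, PHIAnnotation]],
) -> List[LabeledToken]:
    """BIO2 projection: a token whose characters overlap a match inherits
    that match's category; the first token of each match gets B-, later
    ones I-; everything else is O.  Matches must be non-overlapping."""
    _spans_sorted_disjoint([m.span for m in matches])
    ordered = sorted(matches, key=lambda m: m.span.start)
    out: List[LabeledToken] = []
    mi = 0
    prev_match = -1
    for surface, span in tokens:
        while mi < len(ordered) and ordered[mi].span.end <= span.start:
            mi += 1
        assigned = None
        if mi < len(ordered) and ordered[mi].span.overlaps(span):
            assigned = mi
        if assigned is None:
            out.append(LabeledToken(surface, span, "O"))
            prev_match = -1
        else:
            cat = ordered[assigned].category.value
            prefix = "I" if assigned == prev_match else "B"
            out.append(LabeledToken(surface, span, f"{prefix}-{cat}"))
            prev_match = assigned
    return out


def entity_runs(tokens: Sequence[LabeledToken]) -> List[Tuple[str, Span]]:
    """(category, token-hull span) for each B-initiated run."""
    runs: List[Tuple[str, Span]] = []
    for tok in tokens:
        if tok.tag.startswith("B-"):
            runs.append((tok.tag[2:], tok.span))
        elif tok.tag.startswith("I-") and runs:
            cat, hull = runs[-1]
            runs[-1] = (cat, Span(hull.start, tok.span.end))
    return runs


def count_phi_words(notes: Iterable[TaggedNote]) -> Dict[str, int]:
    counts: Dict[str, int] = {c.value: 0 for c in PHICategory}
    for tn in notes:
        for tok in tn.tokens:
            if tok.tag.startswith("B-"):
                counts[tok.tag[2:]] += 1
    return counts


def label_note(note: ClinicalNote, ruleset: RuleSet) -> TaggedNote:
    """Pseudo-label one note: run the rules, project to BIO."""
    matches = apply_rules(note, ruleset)
    return TaggedNote(note, project_to_bio(tokenize(note.text), matches))


def label_note_gold(annotated: AnnotatedNote) -> TaggedNote:
    """Project gold annotations (instead of rule matches) to BIO."""
    note = annotated.note
    return TaggedNote(note, project_to_bio(tokenize(note.text), annotated.annotations))


def sample_corpus(
    labeled: Sequence[TaggedNote],
    tier: Union[Tier, str],
    n_notes: int,
    seed: int,
) -> TaggedCorpus:
    """Keep pre-labeled notes with at least one non-O tag and sample
    ``n_notes`` uniformly without replacement under ``seed``."""
    tier = Tier(tier)
    with_phi = [tn for tn in labeled if any(t.tag != "O" for t in tn.tokens)]
    if n_notes > len(with_phi):
        raise CorpusError(
            f"requested {n_notes} notes but only {len(with_phi)} of "
            f"{len(labeled)} carry at least one rule match"
        )
    rng = random.Random(seed)
    picked = sorted(rng.sample(range(len(with_phi)), n_notes))
    chosen = [with_phi[i] for i in picked]
    return TaggedCorpus(tier=tier, notes=chosen, phi_word_counts=count_phi_words(chosen))


def build_corpus(
    notes: Sequence[ClinicalNote],
    ruleset: RuleSet,
    tier: Union[Tier, str],
    n_notes: int,
    seed: int,
) -> TaggedCorpus:
    """Pseudo-label ``notes``, keep only those with at least one rule match,
    sample ``n_notes`` uniformly without replacement under ``seed``."""
    return sample_corpus([label_note(n, ruleset) for n in notes], tier, n_notes, seed)


def apply_corrections(corpus: TaggedCorpus, corrections: CorrectionList) -> TaggedCorpus:
    """Produce the corrected corpus: removal spans revert their tokens to O
    (a note losing its last annotation is dropped), addition notes are
    appended with gold BIO tags.  Tier becomes large2 when correcting
    large1, custom otherwise."""
    by_id: Dict[str, List[Tuple[str, Span]]] = {}
    for note_id, span in corrections.removals:
        by_id.setdefault(note_id, []).append((note_id, span))

    new_notes: List[TaggedNote] = []
    seen_ids = set()
    for tn in corpus.notes:
        seen_ids.add(tn.note.note_id)
        removals = by_id.pop(tn.note.note_id, [])
        tokens = tn.tokens
        for _, span in removals:
            hit = [i for i, t in enumerate(tokens) if t.span.overlaps(span) and t.tag != "O"]
            if not hit:
                raise CorrectionError(
                    f"removal {span} in note {tn.note.note_id!r} matches no annotation"
                )
            tokens = [
                LabeledToken(t.surface, t.span, "O") if i in hit else t
                for i, t in enumerate(tokens)
            ]
        tokens = repair_bio(tokens)
        if any(t.tag != "O" for t in tokens):
            new_notes.append(TaggedNote(tn.note, list(tokens)))
    if by_id:
        missing = sorted(by_id)
        raise CorrectionError(f"removals reference notes not in corpus: {missing}")

    for annotated in corrections.additions:
        if annotated.note.note_id in seen_ids:
            raise CorrectionError(f"addition duplicates note_id {annotated.note.note_id!r}")
        new_notes.append(label_note_gold(annotated))

    tier = Tier.LARGE2 if corpus.tier is Tier.LARGE1 else Tier.CUSTOM
    return TaggedCorpus(tier=tier, notes=new_notes, phi_word_counts=count_phi_words(new_notes))


def repair_bio(tokens: Sequence[LabeledToken]) -> List[LabeledToken]:
    """Rewrite orphan I-X tokens (after O-reversion) to B-X."""
    out: List[LabeledToken] = []
    prev = "O"
    for t in tokens:
        tag = t.tag
        if tag.startswith("I-") and prev not in (f"B-{tag[2:]}", tag):
            tag = "B-" + tag[2:]
        out.append(LabeledToken(t.surface, t.span, tag) if tag != t.tag else t)
        prev = tag
    return out


def corrections_from_gold(
    corpus: TaggedCorpus, gold: Dict[str, Sequence[PHIAnnotation]]
) -> CorrectionList:
    """Flag pseudo-label entities with no gold overlap as false positives.

    Emulates the manual corpus-correction pass: every B-initiated run whose
    token hull overlaps no gold annotation of its note becomes a removal.
    """
    removals: List[Tuple[str, Span]] = []
    for tn in corpus.notes:
        gold_spans = [a.span for a in gold.get(tn.note.note_id, [])]
        for _, hull in entity_runs(tn.tokens):
            if not any(hull.overlaps(g) for g in gold_spans):
                removals.append((tn.note.note_id, hull))
    return CorrectionList(removals=removals)
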