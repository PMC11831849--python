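"""Token-level per-category and micro-total precision/recall/F1.

Scoring is per token with B/I collapsed to the bare category: a token is a
true positive when gold and prediction agree on a non-O category; a non-O
prediction disagreeing with gold counts as a false positive for the
predicted category; a non-O gold token missed or mis-categorized counts as
a false negative for the gold category (so a cross-category confusion is
one FP and one FN, keeping per-category marginals consistent).  O/O tokens
are ignored.  0/0 ratios are defined as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence

from .core import PHICategory
from .errors import AlignmentError
from .pseudo_label import LabeledToken, TaggedNote

CATEGORIES = [c.value for c in PHICategory]


@dataclass
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    per_category: Dict[str, CategoryCounts] = field(default_factory=dict)

    @property
    def micro(self) -> CategoryCounts:
        return CategoryCounts(
            tp=sum(c.tp for c in self.per_category.values()),
            fp=sum(c.fp for c in self.per_category.values()),
            fn=sum(c.fn for c in self.per_category.values()),
        )

    def to_dict(self, rounded: bool = False) -> dict:
        def row(c: CategoryCounts) -> dict:
            p, r, f = c.precision, c.recall, c.f1
            if rounded:
                p, r, f = round2(p), round2(r), round2(f)
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "precision": p, "recall": r, "f1": f}

        out = {cat: row(c) for cat, c in self.per_category.items()}
        out["Total"] = row(self.micro)
        return out

    def to_json(self, rounded: bool = False) -> str:
        return json.dumps(self.to_dict(rounded=rounded), indent=2, sort_keys=True)

    def render_table(self) -> str:
        """Plain-text table in the per-category P/R/F1 layout."""
        lines = [f"{'':8s}{'Precision':>10s}{'Recall':>10s}{'F1 Score':>10s}"]
        data = self.to_dict(rounded=True)
        for cat in CATEGORIES + ["Total"]:
            if cat in data:
                r = data[cat]
                lines.append(f"{cat:8s}{r['precision']:>10.2f}{r['recall']:>10.2f}{r['f1']:>10.2f}")
        return "\n".join(lines)


def round2(x: float) -> float:
    """Round half-up to 2 decimals, matching printed-table convention."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def token_confusion(
    gold: Sequence[LabeledToken], pred: Sequence[LabeledToken]
) -> Dict[str, CategoryCounts]:
    """Per-category TP/FP/FN over one aligned token sequence."""
    if len(gold) != len(pred):
        raise AlignmentError(f"token count mismatch: gold {len(gold)} vs pred {len(pred)}")
    counts = {c: CategoryCounts() for c in CATEGORIES}
    for g, p in zip(gold, pred):
        if g.span != p.span:
            raise AlignmentError(f"token misalignment at gold {g.span} vs pred {p.span}")
        gc, pc = g.category, p.category
        if gc is None and pc is None:
            continue
        if gc == pc:
            counts[gc].tp += 1
        else:
            if pc is not None:
                counts[pc].fp += 1
            if gc is not None:
                counts[gc].fn += 1
    return counts


def merge_counts(parts: Sequence[Dict[str, CategoryCounts]]) -> Dict[str, CategoryCounts]:
    total = {c: CategoryCounts() for c in CATEGORIES}
    for part in parts:
        for cat, c in part.items():
            total[cat].tp += c.tp
            total[cat].fp += c.fp
            total[cat].fn += c.fn
    return total


def compute_metrics(counts: Dict[str, CategoryCounts]) -> EvalReport:
    for cat, c in counts.items():
        if min(c.tp, c.fp, c.fn) < 0:
            raise ValueError(f"negative counts for {cat}")
    return EvalReport(per_category=dict(counts))


def evaluate(gold_notes: Sequence[TaggedNote], pred_notes: Sequence[TaggedNote]) -> EvalReport:
    """Token-level evaluation over matched note sets (by note_id)."""
    gold_by_id = {tn.note.note_id: tn for tn in gold_notes}
    pred_by_id = {tn.note.note_id: tn for tn in pred_notes}
    missing = sorted(set(gold_by_id) ^ set(pred_by_id))
    if missing:
        raise AlignmentError(f"note sets differ; unmatched note_ids: {missing[:10]}")
    parts: List[Dict[str, CategoryCounts]] = []
    for note_id in gold_by_id:
        parts.append(token_confusion(gold_by_id[note_id].tokens, pred_by_id[note_id].tokens))
    return compute_metrics(merge_counts(parts))
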